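"""Read-to-gene assignment, filtering and FPKM quantification.

The assigner reproduces the two filtering semantics of a standard
align-then-filter chain (drop unmapped reads; drop ambiguous/low-confidence
multi-mappers) with a deterministic exact-seed-and-extend matcher suited to
the synthetic, substitution-only reads this package simulates:

* a read matching no gene within ``max_mismatches`` is **unassigned**
  (the analog of dropping flag-4 unmapped records);
* a read matching two or more genes equally well is **ambiguous** and
  discarded (the analog of a MAPQ cutoff removing multi-mappers);
* ties are always discarded, never broken randomly.

Real count tables (TSV) or alignments (BAM, mapping quality >= 30, primary
records only) can be imported directly, bypassing the matcher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InconsistencyError, InvalidInputError, MappedTotalZeroError
from .simulate import GeneModel, ReadSet, SCREEN_LABELS

logger = logging.getLogger(__name__)


@dataclass
class CountTable:
    """Per-gene assigned read counts for one screen, with assignment tallies."""

    screen_label: str
    counts: dict[str, int]
    n_assigned: int
    n_ambiguous: int
    n_unassigned: int

    def __post_init__(self) -> None:
        if self.screen_label not in SCREEN_LABELS:
            raise InvalidInputError(f"screen_label must be one of {SCREEN_LABELS}")
        if any(c < 0 for c in self.counts.values()):
            raise InvalidInputError("counts must be non-negative")
        if self.n_assigned != sum(self.counts.values()):
            raise InconsistencyError("n_assigned must equal the sum of counts")
        if min(self.n_ambiguous, self.n_unassigned) < 0:
            raise InvalidInputError("tallies must be non-negative")

    @property
    def total_input_reads(self) -> int:
        return self.n_assigned + self.n_ambiguous + self.n_unassigned

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.counts), "count": list(self.counts.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FPKMTable:
    """Fragments per kilobase of gene model per million mapped fragments."""

    screen_label: str
    fpkm: dict[str, float]
    mapped_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": list(self.fpkm), "fpkm": list(self.fpkm.values())})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _build_seed_index(
    library: Sequence[GeneModel], k: int
) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for gi, gene in enumerate(library):
        seq = gene.cds_seq
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((gi, pos))
    return index


def _hamming_leq(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or limit+1 once exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def assign_reads(
    reads: ReadSet,
    library: Sequence[GeneModel],
    min_seed_len: int = 20,
    max_mismatches: int = 2,
) -> CountTable:
    """Assign each read to its best-matching gene.

    Non-overlapping exact seeds of length ``min_seed_len`` are looked up in a
    k-mer index and extended to a full-read Hamming comparison.  With
    ``floor(read_length / min_seed_len) > max_mismatches`` seeds, the
    pigeonhole principle guarantees every true match is found.
    """
    if not library:
        raise InvalidInputError("empty library")
    for g in library:
        if g.cds_seq is None:
            raise InvalidInputError(f"{g.gene_id}: library genes must carry CDS sequences")
    k = min_seed_len
    if k < 1:
        raise InvalidInputError("min_seed_len must be >= 1")
    index = _build_seed_index(library, k)
    gene_seqs = [g.cds_seq for g in library]
    gene_lens = [g.length_bp for g in library]

    counts: dict[str, int] = {}
    n_ambiguous = 0
    n_unassigned = 0
    short_warned = False
    for seq in reads.sequences:
        L = len(seq)
        if L < k:
            if not short_warned:
                logger.warning("reads shorter than min_seed_len=%d are left unassigned", k)
                short_warned = True
            n_unassigned += 1
            continue
        offsets = list(range(0, L - k + 1, k))
        candidates: set[tuple[int, int]] = set()
        for off in offsets:
            for gi, pos in index.get(seq[off:off + k], ()):
                start = pos - off
                if 0 <= start <= gene_lens[gi] - L:
                    candidates.add((gi, start))
        best_d = max_mismatches + 1
        best_genes: set[int] = set()
        for gi, start in candidates:
            d = _hamming_leq(seq, gene_seqs[gi][start:start + L], max_mismatches)
            if d < best_d:
                best_d = d
                best_genes = {gi}
            elif d == best_d:
                best_genes.add(gi)
        if best_d > max_mismatches or not best_genes:
            n_unassigned += 1
        elif len(best_genes) > 1:
            n_ambiguous += 1
        else:
            gid = library[best_genes.pop()].gene_id
            counts[gid] = counts.get(gid, 0) + 1

    return CountTable(
        screen_label=reads.screen_label,
        counts=counts,
        n_assigned=sum(counts.values()),
        n_ambiguous=n_ambiguous,
        n_unassigned=n_unassigned,
    )


def compute_fpkm(counts: CountTable, library: Sequence[GeneModel]) -> FPKMTable:
    """FPKM[g] = counts[g] * 1e9 / (length_bp[g] * mapped_total).

    The denominator is the number of reads assigned after all filters ("per
    million *mapped* fragments"); single-end reads, so fragments == reads.
    Every library gene appears in the output (zero counts give FPKM 0).
    """
    lengths = {g.gene_id: g.length_bp for g in library}
    missing = [g for g in counts.counts if g not in lengths]
    if missing:
        raise InvalidInputError(f"counted genes without a library length: {missing[:5]}")
    mapped_total = counts.n_assigned
    if mapped_total == 0:
        raise MappedTotalZeroError(
            f"{counts.screen_label} screen: zero assigned reads, FPKM undefined"
        )
    fpkm = {
        gid: counts.counts.get(gid, 0) * 1e9 / (length * mapped_total)
        for gid, length in lengths.items()
    }
    return FPKMTable(screen_label=counts.screen_label, fpkm=fpkm, mapped_total=mapped_total)


def counts_from_tsv(path, screen_label: str) -> CountTable:
    """Import an external two-column (gene_id, count) TSV as a CountTable.

    Ambiguous/unassigned tallies are unknown for external counts and set to 0.
    """
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "count"} <= set(df.columns):
        raise InvalidInputError("counts TSV must have columns gene_id, count")
    counts = {str(g): int(c) for g, c in zip(df["gene_id"], df["count"])}
    return CountTable(screen_label=screen_label, counts=counts,
                      n_assigned=sum(counts.values()), n_ambiguous=0, n_unassigned=0)


def counts_from_bam(path, library: Sequence[GeneModel], screen_label: str,
                    min_mapq: int = 30) -> CountTable:
    """Import per-gene counts from a SAM/BAM of reads aligned to the CDS set.

    Primary alignments with mapping quality >= ``min_mapq`` are counted to
    their reference; unmapped records are tallied unassigned and mapped
    records below the cutoff (multi-mappers) ambiguous.
    """
    import pysam

    known = {g.gene_id for g in library}
    counts: dict[str, int] = {}
    n_ambiguous = 0
    n_unassigned = 0
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                n_unassigned += 1
            elif rec.mapping_quality < min_mapq:
                n_ambiguous += 1
            else:
                ref = rec.reference_name
                if ref not in known:
                    raise InvalidInputError(f"alignment reference {ref!r} not in library")
                counts[ref] = counts.get(ref, 0) + 1
    return CountTable(screen_label=screen_label, counts=counts,
                      n_assigned=sum(counts.values()),
                      n_ambiguous=n_ambiguous, n_unassigned=n_unassigned)
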