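"""Synthetic pooled Y2H selection screens with ground truth.

This module emulates the wet workflow of a pooled mating-based split-ubiquitin
two-hybrid screen read out by short-read sequencing: a cDNA prey library is
transformed against either a bait of interest (``BAIT``) or an empty bait
vector (``EMPTY``); colonies surviving nutritional selection are picked in
pools, PCR-amplified, and sequenced as one mixed sample per screen.

Two colony-level artifact processes generate false positives in real screens
and are modelled explicitly:

* **self-activation** — a prey that triggers reporter growth without any
  genuine interaction survives in both screens;
* **multi-plasmid colonies** — a colony taking up two prey plasmids survives
  if either qualifies, so the second ("hitchhiker") insert is sequenced too.

Everything is generated from a single integer seed, and ground truth
(interactor / self-activator flags, library abundances) is returned alongside
so downstream calling can be benchmarked.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError, SimulationExhaustedError

logger = logging.getLogger(__name__)

BAIT = "BAIT"
EMPTY = "EMPTY"
SCREEN_LABELS = (BAIT, EMPTY)

_BASES = np.array(list("ACGT"))

# Standard codon choices per residue (no stop codons; CDS length = 3 * n_aa).
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_RESIDUES = sorted(_CODONS)

# Hydrophilic-biased residue frequencies for soluble (non-membrane) stretches.
_SOLUBLE_WEIGHTS = {
    "A": 1.0, "C": 0.4, "D": 1.5, "E": 1.6, "F": 0.5, "G": 1.3, "H": 0.7,
    "I": 0.5, "K": 1.5, "L": 0.8, "M": 0.4, "N": 1.2, "P": 1.2, "Q": 1.2,
    "R": 1.3, "S": 1.6, "T": 1.3, "V": 0.6, "W": 0.3, "Y": 0.8,
}
# Strongly hydrophobic pool used inside designed membrane-spanning segments.
_TM_WEIGHTS = {"L": 3.0, "I": 2.5, "V": 2.0, "F": 1.5, "A": 1.5, "M": 0.8, "W": 0.3, "G": 0.5, "T": 0.4, "S": 0.4}
_TM_SEGMENT_LEN = 21


@dataclass(frozen=True)
class GeneModel:
    """One prey-library gene: identifier, CDS length and optional sequences."""

    gene_id: str
    length_bp: int
    cds_seq: str | None = None
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise InvalidInputError(f"{self.gene_id}: length_bp must be positive")
        if self.cds_seq is not None and len(self.cds_seq) != self.length_bp:
            raise InvalidInputError(
                f"{self.gene_id}: cds_seq length {len(self.cds_seq)} != length_bp {self.length_bp}"
            )


@dataclass
class ScreenTruth:
    """Simulator ground truth for one library.

    ``abundance`` is the relative plasmid frequency of each gene in the prey
    library and sums to one; a gene may be both interactor and self-activator.
    """

    gene_ids: list[str]
    is_interactor: np.ndarray
    is_self_activator: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise InvalidInputError("gene_ids must be unique")
        self.is_interactor = np.asarray(self.is_interactor, dtype=bool)
        self.is_self_activator = np.asarray(self.is_self_activator, dtype=bool)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if not (len(self.is_interactor) == len(self.is_self_activator) == len(self.abundance) == n):
            raise InvalidInputError("truth arrays must all have one entry per gene")
        if np.any(self.abundance < 0):
            raise InvalidInputError("abundances must be non-negative")
        if abs(float(self.abundance.sum()) - 1.0) > 1e-9:
            raise InvalidInputError("abundances must sum to 1 (tolerance 1e-9)")

    @property
    def interactors(self) -> set[str]:
        return {g for g, f in zip(self.gene_ids, self.is_interactor) if f}

    @property
    def self_activators(self) -> set[str]:
        return {g for g, f in zip(self.gene_ids, self.is_self_activator) if f}

    @property
    def pure_interactors(self) -> set[str]:
        """Interactors that are not also self-activators (callable by design)."""
        return {
            g
            for g, i, s in zip(self.gene_ids, self.is_interactor, self.is_self_activator)
            if i and not s
        }

    @property
    def pure_self_activators(self) -> set[str]:
        return {
            g
            for g, i, s in zip(self.gene_ids, self.is_interactor, self.is_self_activator)
            if s and not i
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "is_interactor": self.is_interactor.astype(int),
                "is_self_activator": self.is_self_activator.astype(int),
                "abundance": self.abundance,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScreenTruth":
        df = pd.read_csv(path, sep="\t")
        return cls(
            gene_ids=df["gene_id"].astype(str).tolist(),
            is_interactor=df["is_interactor"].to_numpy(dtype=bool),
            is_self_activator=df["is_self_activator"].to_numpy(dtype=bool),
            abundance=df["abundance"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative screen model.

    The defaults describe the package's demonstration screen: 500 library
    genes, 5% true interactors under stringent selection, 2% self-activators,
    1200 picked colonies per screen and 1e5 reads per screen.  Artifact rates
    (multi-plasmid co-transformation, selection leak-through) default to the
    rare-event regime of a stringent double-dropout selection; unit tests
    exercise them at elevated rates.
    """

    n_genes: int = 500
    n_colonies_picked: int = 1200
    pool_size: int = 10
    multi_plasmid_prob: float = 2e-4
    leak_prob: float = 2e-5
    pcr_amplification_cv: float = 0.3
    read_length: int = 75
    total_reads: int = 100_000
    seq_error_rate: float = 0.001
    seed: int = 0
    # library composition
    interactor_fraction: float = 0.05
    self_activator_fraction: float = 0.02
    abundance_sigma: float = 1.0
    tm_fraction: float = 0.30
    tm_abundance_multiplier: float = 1.0
    # protein/CDS length model (residues); CDS length = 3 * n_aa
    mean_protein_length: int = 400
    protein_length_sigma: float = 0.25
    min_protein_length: int = 80

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if self.pool_size < 1:
            raise InvalidConfigError("pool_size must be >= 1")
        if self.n_colonies_picked < 0:
            raise InvalidConfigError("n_colonies_picked must be >= 0")
        for name in ("multi_plasmid_prob", "leak_prob", "seq_error_rate",
                     "interactor_fraction", "self_activator_fraction", "tm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.pcr_amplification_cv < 0:
            raise InvalidConfigError("pcr_amplification_cv must be >= 0")
        if self.total_reads < 0:
            raise InvalidConfigError("total_reads must be >= 0")
        if self.read_length < 1:
            raise InvalidConfigError("read_length must be >= 1")
        if self.tm_abundance_multiplier <= 0:
            raise InvalidConfigError("tm_abundance_multiplier must be > 0")
        if 3 * self.min_protein_length < self.read_length:
            raise InvalidConfigError(
                "read_length exceeds the minimum simulated CDS length "
                f"({3 * self.min_protein_length} bp); shorten reads or raise min_protein_length"
            )

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ReadSet:
    """Simulated single-end reads from one screen.

    ``origins`` is parallel ground truth (the source gene of each read); it is
    written to a separate provenance table, never into the FASTQ itself, so the
    pipeline under test cannot see it.
    """

    screen_label: str
    read_length: int
    read_ids: list[str]
    sequences: list[str]
    origins: list[str]
    # realized per-gene sampling mass (amplified copies x length), provenance only
    gene_read_mass: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.screen_label not in SCREEN_LABELS:
            raise InvalidInputError(f"screen_label must be one of {SCREEN_LABELS}")
        if not (len(self.read_ids) == len(self.sequences) == len(self.origins)):
            raise InvalidInputError("read_ids, sequences and origins must be parallel")
        for s in self.sequences:
            if len(s) != self.read_length:
                raise InvalidInputError("every read must have length read_length")

    def __len__(self) -> int:
        return len(self.read_ids)

    def to_fastq(self, path) -> None:
        """Write reads as FASTQ with a constant quality string (qualities are
        never used downstream)."""
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for rid, seq in zip(self.read_ids, self.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"read_id": self.read_ids, "origin_gene_id": self.origins})

    @classmethod
    def from_fastq(cls, path, screen_label: str) -> "ReadSet":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not seqs:
            raise InvalidInputError(f"no reads in {path}")
        rl = len(seqs[0])
        return cls(screen_label=screen_label, read_length=rl, read_ids=ids,
                   sequences=seqs, origins=[""] * len(ids))


def _weighted_residues(rng: np.random.Generator, n: int, weights: dict[str, float]) -> np.ndarray:
    res = np.array(sorted(weights))
    p = np.array([weights[r] for r in sorted(weights)], dtype=float)
    p /= p.sum()
    return rng.choice(res, size=n, p=p)


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein)


def _design_protein(rng: np.random.Generator, n_aa: int, is_tm: bool) -> str:
    aa = _weighted_residues(rng, n_aa, _SOLUBLE_WEIGHTS)
    if is_tm and n_aa >= _TM_SEGMENT_LEN + 10:
        n_seg = int(rng.integers(1, 4))
        # place segments on a coarse grid to keep them non-overlapping
        slots = max(1, (n_aa - 10) // (_TM_SEGMENT_LEN + 10))
        n_seg = min(n_seg, slots)
        chosen = rng.choice(slots, size=n_seg, replace=False)
        for s in sorted(chosen):
            start = 5 + s * (_TM_SEGMENT_LEN + 10)
            aa[start:start + _TM_SEGMENT_LEN] = _weighted_residues(
                rng, _TM_SEGMENT_LEN, _TM_WEIGHTS
            )
    return "".join(aa)


def generate_library(config: SimConfig) -> tuple[list[GeneModel], ScreenTruth]:
    """Generate a synthetic prey library with ground truth.

    CDS sequences are random back-translations of designed proteins; a
    reject-and-resample step guarantees that no exact ``read_length``-mer is
    shared between two genes, so a read can only be ambiguous through
    sequencing error.  Library abundances are lognormal (heavy-tailed, as cDNA
    libraries are), optionally boosted for designed-membrane genes, then
    normalized to sum to one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    k = config.read_length

    lengths_aa = np.maximum(
        config.min_protein_length,
        np.rint(rng.lognormal(math.log(config.mean_protein_length),
                              config.protein_length_sigma, size=n)).astype(int),
    )
    is_tm = rng.random(n) < config.tm_fraction

    genes: list[GeneModel] = []
    seen_kmers: set[str] = set()
    width = max(4, len(str(n)))
    for i in range(n):
        gene_id = f"g{i + 1:0{width}d}"
        for attempt in range(50):
            protein = _design_protein(rng, int(lengths_aa[i]), bool(is_tm[i]))
            cds = _back_translate(protein, rng)
            kmers = {cds[j:j + k] for j in range(len(cds) - k + 1)}
            if seen_kmers.isdisjoint(kmers):
                seen_kmers |= kmers
                genes.append(GeneModel(gene_id=gene_id, length_bp=len(cds),
                                       cds_seq=cds, protein_seq=protein))
                break
        else:  # pragma: no cover - astronomically unlikely for random CDS
            raise InvalidConfigError(
                f"could not sample a collision-free CDS for {gene_id} after 50 attempts"
            )

    is_interactor = rng.random(n) < config.interactor_fraction
    is_self_activator = rng.random(n) < config.self_activator_fraction
    abundance = rng.lognormal(0.0, config.abundance_sigma, size=n)
    if config.tm_abundance_multiplier != 1.0:
        abundance = abundance * np.where(is_tm, config.tm_abundance_multiplier, 1.0)
    abundance = abundance / abundance.sum()

    truth = ScreenTruth(
        gene_ids=[g.gene_id for g in genes],
        is_interactor=is_interactor,
        is_self_activator=is_self_activator,
        abundance=abundance,
    )
    return genes, truth


def _sample_colonies(
    truth: ScreenTruth, config: SimConfig, qualifies: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    """Draw colonies until ``n_colonies_picked`` survive selection.

    A colony carries one prey plasmid (prob 1-m) or two distinct plasmids
    (prob m), drawn by library abundance.  It survives iff it carries at least
    one qualifying gene, or leaks through selection with probability ``leak_prob``.
    """
    n_needed = config.n_colonies_picked
    survivors: list[tuple[int, ...]] = []
    max_draws = 2000 * max(n_needed, 1) + 100_000
    draws_done = 0
    n_genes = len(truth.gene_ids)
    p = truth.abundance
    while len(survivors) < n_needed:
        if draws_done >= max_draws:
            raise SimulationExhaustedError(
                f"only {len(survivors)}/{n_needed} surviving colonies after "
                f"{draws_done} draws; selection too stringent for this library"
            )
        batch = min(max_draws - draws_done, max(4 * (n_needed - len(survivors)), 1000))
        draws_done += batch
        first = rng.choice(n_genes, size=batch, p=p)
        is_multi = rng.random(batch) < config.multi_plasmid_prob
        second = rng.choice(n_genes, size=batch, p=p)
        leak = rng.random(batch) < config.leak_prob
        for j in range(batch):
            plasmids: tuple[int, ...]
            if is_multi[j]:
                s = int(second[j])
                while s == int(first[j]):  # two *distinct* plasmids
                    s = int(rng.choice(n_genes, p=p))
                plasmids = (int(first[j]), s)
            else:
                plasmids = (int(first[j]),)
            if any(qualifies[g] for g in plasmids) or leak[j]:
                survivors.append(plasmids)
                if len(survivors) == n_needed:
                    break
    return survivors


def simulate_screen(
    library: Sequence[GeneModel],
    truth: ScreenTruth,
    config: SimConfig,
    screen_label: str,
) -> ReadSet:
    """Simulate one pooled selection screen down to reads.

    Survivor colonies are picked, each colony's inserts are amplified by an
    independent lognormal PCR factor (CV = ``pcr_amplification_cv``), and
    ``total_reads`` single-end reads are sampled with probability proportional
    to amplified copy number x gene length (fragmentation proportional to
    length, so FPKM is unbiased).  Each read is a uniform substring of the
    gene CDS with per-base substitution rate ``seq_error_rate``.
    """
    config.validate()
    if screen_label not in SCREEN_LABELS:
        raise InvalidInputError(f"screen_label must be one of {SCREEN_LABELS}")
    if [g.gene_id for g in library] != truth.gene_ids:
        if sorted(g.gene_id for g in library) != sorted(truth.gene_ids):
            raise InvalidInputError("library and truth must cover identical gene ids")
        order = {g: i for i, g in enumerate(truth.gene_ids)}
        library = sorted(library, key=lambda g: order[g.gene_id])
    for g in library:
        if g.cds_seq is None:
            raise InvalidInputError(f"{g.gene_id}: CDS sequence required for read simulation")
        if g.length_bp < config.read_length:
            raise InvalidInputError(
                f"{g.gene_id}: length {g.length_bp} < read_length {config.read_length}"
            )

    # independent stream per screen so BAIT and EMPTY are uncorrelated
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(SCREEN_LABELS.index(screen_label),))
    )
    qualifies = (
        truth.is_self_activator | truth.is_interactor
        if screen_label == BAIT
        else truth.is_self_activator.copy()
    )
    colonies = _sample_colonies(truth, config, qualifies, rng)
    logger.info("%s screen: %d surviving colonies picked (%d pools of %d)",
                screen_label, len(colonies), -(-len(colonies) // config.pool_size),
                config.pool_size)

    n_genes = len(library)
    weight = np.zeros(n_genes)
    if config.pcr_amplification_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.pcr_amplification_cv ** 2))
        factors = rng.lognormal(-0.5 * sigma * sigma, sigma, size=len(colonies))
    else:
        factors = np.ones(len(colonies))
    for fac, plasmids in zip(factors, colonies):
        for g in plasmids:
            weight[g] += fac

    lengths = np.array([g.length_bp for g in library], dtype=float)
    mass = weight * lengths
    prefix = "b" if screen_label == BAIT else "e"
    mass_by_gene = {g.gene_id: float(m) for g, m in zip(library, mass) if m > 0}
    if config.total_reads == 0 or mass.sum() == 0:
        return ReadSet(screen_label=screen_label, read_length=config.read_length,
                       read_ids=[], sequences=[], origins=[],
                       gene_read_mass=mass_by_gene)
    counts = rng.multinomial(config.total_reads, mass / mass.sum())

    L = config.read_length
    seqs: list[str] = []
    origins: list[str] = []
    for gi in np.nonzero(counts)[0]:
        gene = library[gi]
        c = int(counts[gi])
        starts = rng.integers(0, gene.length_bp - L + 1, size=c)
        arr = np.frombuffer(gene.cds_seq.encode(), dtype="S1")
        idx = starts[:, None] + np.arange(L)[None, :]
        reads = arr[idx]
        if config.seq_error_rate > 0:
            err = rng.random((c, L)) < config.seq_error_rate
            n_err = int(err.sum())
            if n_err:
                subs = _BASES[rng.integers(0, 3, size=n_err)]
                flat = reads.astype("U1")
                cur = flat[err]
                # substitute with a base different from the original
                new = np.where(subs == cur, "T", subs)
                new = np.where((subs == cur) & (cur == "T"), "A", new)
                flat[err] = new
                reads = flat
            else:
                reads = reads.astype("U1")
        else:
            reads = reads.astype("U1")
        seqs.extend("".join(row) for row in reads)
        origins.extend([gene.gene_id] * c)

    perm = rng.permutation(len(seqs))
    seqs = [seqs[i] for i in perm]
    origins = [origins[i] for i in perm]
    width = len(str(max(len(seqs), 1)))
    ids = [f"{prefix}{i + 1:0{width}d}" for i in range(len(seqs))]
    return ReadSet(screen_label=screen_label, read_length=L,
                   read_ids=ids, sequences=seqs, origins=origins,
                   gene_read_mass=mass_by_gene)


def generate_annotations(
    library: Sequence[GeneModel],
    truth: ScreenTruth,
    seed: int,
    p_term_given_interactor: float = 0.6,
    p_term_background: float = 0.08,
    n_random_terms: int = 5,
    p_random_term: float = 0.10,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Synthetic GO-like gene->term annotations for the demo pipeline.

    One "transporter activity"-style term is enriched among true interactors
    (the biological signal the screen is meant to surface); the remaining terms
    are unstructured background.
    """
    rng = np.random.default_rng(seed)
    interactors = truth.interactors
    annotation: dict[str, set[str]] = {}
    names: dict[str, str] = {"T:0001": "transmembrane transporter activity"}
    transporter = set()
    for g in library:
        p = p_term_given_interactor if g.gene_id in interactors else p_term_background
        if rng.random() < p:
            transporter.add(g.gene_id)
    annotation["T:0001"] = transporter
    for t in range(n_random_terms):
        tid = f"T:{t + 2:04d}"
        names[tid] = f"background process {t + 1}"
        annotation[tid] = {g.gene_id for g in library if rng.random() < p_random_term}
    return annotation, names


def simulate_proteome(
    protein_ids: Sequence[str],
    seed: int,
    n_reps: int = 3,
    up_ids: Iterable[str] | None = None,
    down_ids: Iterable[str] | None = None,
    frac_up: float = 0.10,
    frac_down: float = 0.25,
    planted_log2fc: float = 2.0,
    replicate_cv: float = 0.10,
    base_sigma: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic replicate abundance table for a deletion-vs-control proteome.

    Each protein gets a lognormal base abundance; replicates add lognormal
    noise with coefficient of variation ``replicate_cv``; proteins planted
    up/down have their mutant-group mean multiplied by ``2**(+/-planted_log2fc)``.
    Returns (abundance table with columns protein_id, c1..cN, m1..mN) and a
    truth table with the planted class.
    """
    if n_reps < 2:
        raise InvalidConfigError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    ids = list(protein_ids)
    n = len(ids)
    if up_ids is None or down_ids is None:
        classes = np.array(["NS"] * n, dtype=object)
        r = rng.random(n)
        classes[r < frac_up] = "UP"
        classes[(r >= frac_up) & (r < frac_up + frac_down)] = "DOWN"
    else:
        up_ids, down_ids = set(up_ids), set(down_ids)
        if up_ids & down_ids:
            raise InvalidInputError("a protein cannot be planted both UP and DOWN")
        classes = np.array(
            ["UP" if p in up_ids else "DOWN" if p in down_ids else "NS" for p in ids],
            dtype=object,
        )
    base = rng.lognormal(math.log(1e5), base_sigma, size=n)
    sigma = math.sqrt(math.log(1.0 + replicate_cv ** 2))
    shift = np.where(classes == "UP", planted_log2fc, np.where(classes == "DOWN", -planted_log2fc, 0.0))
    ctrl = base[:, None] * rng.lognormal(-0.5 * sigma**2, sigma, size=(n, n_reps))
    mut = (base * 2.0 ** shift)[:, None] * rng.lognormal(-0.5 * sigma**2, sigma, size=(n, n_reps))
    table = pd.DataFrame({"protein_id": ids})
    for j in range(n_reps):
        table[f"c{j + 1}"] = ctrl[:, j]
    for j in range(n_reps):
        table[f"m{j + 1}"] = mut[:, j]
    truth = pd.DataFrame({"protein_id": ids, "planted": classes, "planted_log2fc": shift})
    return table, truth


def write_library_fasta(library: Sequence[GeneModel], cds_path, protein_path=None) -> None:
    """Write CDS (and optionally protein) FASTA for a library."""
    with open(cds_path, "w") as fh:
        for g in library:
            fh.write(f">{g.gene_id}\n{g.cds_seq}\n")
    if protein_path is not None:
        with open(protein_path, "w") as fh:
            for g in library:
                if g.protein_seq is not None:
                    fh.write(f">{g.gene_id}\n{g.protein_seq}\n")


def read_library_fasta(cds_path, protein_path=None) -> list[GeneModel]:
    from Bio import SeqIO

    proteins: dict[str, str] = {}
    if protein_path is not None:
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_path), "fasta")}
    genes = []
    for rec in SeqIO.parse(str(cds_path), "fasta"):
        seq = str(rec.seq).upper()
        genes.append(GeneModel(gene_id=rec.id, length_bp=len(seq), cds_seq=seq,
                               protein_seq=proteins.get(rec.id)))
    if not genes:
        raise InvalidInputError(f"no sequences in {cds_path}")
    return genes
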