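"""Transmembrane-segment annotation and the TM-fraction-by-FPKM analysis.

Membrane-spanning helices are detected with the classic Kyte-Doolittle
sliding-window hydropathy scan (window 19, threshold 1.6 — the combination
Kyte & Doolittle recommended for integral-membrane segments).  A protein with
at least one segment is classed transmembrane.  Precomputed annotations from
any external predictor can be imported instead; downstream analyses use only
the binary flag and segment count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import InteractorCall
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class TMAnnotation:
    """Predicted or imported transmembrane segments of one protein."""

    gene_id: str
    n_tm_segments: int
    segments: list[tuple[int, int]]  # 1-based inclusive residue intervals
    source: str = "PREDICTED"  # or IMPORTED

    def __post_init__(self) -> None:
        if self.n_tm_segments < 0:
            raise InvalidInputError("n_tm_segments must be non-negative")
        if self.source not in ("PREDICTED", "IMPORTED"):
            raise InvalidInputError("source must be PREDICTED or IMPORTED")
        last_end = 0
        for start, end in self.segments:
            if start <= last_end:
                raise InvalidInputError("segments must be sorted and non-overlapping")
            last_end = end

    @property
    def is_transmembrane(self) -> bool:
        return self.n_tm_segments >= 1


def predict_tm_segments(
    protein_seq: str,
    window: int = 19,
    threshold: float = 1.6,
    gene_id: str = "",
) -> TMAnnotation:
    """Kyte-Doolittle sliding-window transmembrane segment prediction.

    The mean hydropathy of every length-``window`` window is computed;
    maximal runs of consecutive above-threshold windows are merged into one
    segment whose boundaries are the outermost window extents (so every
    segment spans at least ``window`` residues).  Residues outside the 20
    standard amino acids score 0 (with a warning); sequences shorter than the
    window yield zero segments.
    """
    seq = protein_seq.strip().upper()
    if window < 1:
        raise InvalidInputError("window must be >= 1")
    n = len(seq)
    if n < window:
        logger.warning("%s: sequence length %d < window %d; no segments called",
                       gene_id or "<anon>", n, window)
        return TMAnnotation(gene_id=gene_id, n_tm_segments=0, segments=[])
    nonstandard = {c for c in seq if c not in KYTE_DOOLITTLE}
    if nonstandard:
        logger.warning("%s: non-standard residues %s scored 0",
                       gene_id or "<anon>", sorted(nonstandard))
    scores = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    window_means = np.convolve(scores, np.ones(window) / window, mode="valid")
    above = window_means > threshold

    extents: list[tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            extents.append((i + 1, j + window))  # 1-based inclusive extents
            i = j + 1
        else:
            i += 1
    # nearby runs have overlapping window extents: one physical helix
    segments: list[tuple[int, int]] = []
    for start, end in extents:
        if segments and start <= segments[-1][1]:
            segments[-1] = (segments[-1][0], max(segments[-1][1], end))
        else:
            segments.append((start, end))
    return TMAnnotation(gene_id=gene_id, n_tm_segments=len(segments), segments=segments)


def annotate_library(
    proteins: Mapping[str, str], window: int = 19, threshold: float = 1.6
) -> dict[str, TMAnnotation]:
    """Predict TM segments for a gene_id -> protein sequence mapping."""
    return {
        gid: predict_tm_segments(seq, window=window, threshold=threshold, gene_id=gid)
        for gid, seq in proteins.items()
    }


def fpkm_bin_tm_fraction(
    calls: Sequence[InteractorCall],
    annotations: Mapping[str, TMAnnotation] | Iterable[TMAnnotation],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Fraction of transmembrane proteins per bait-FPKM bin of accepted genes.

    Bins are half-open ``[e_i, e_{i+1})``; the final bin is closed on the
    right.  Empty bins are reported with ``fraction_tm`` NaN (undefined).
    Accepted genes with FPKM outside the outermost edges are not binned.
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.gene_id: a for a in annotations}
    edges = list(bin_edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise InvalidInputError("bin_edges must be strictly increasing with >= 2 values")
    accepted = [c for c in calls if c.accepted]
    missing = sorted(c.gene_id for c in accepted if c.gene_id not in annotations)
    if missing:
        raise InvalidInputError(f"accepted genes without a TM annotation: {missing}")

    n_bins = len(edges) - 1
    n_tm = [0] * n_bins
    n_non = [0] * n_bins
    for c in accepted:
        x = c.fpkm_bait
        if x < edges[0] or x > edges[-1]:
            continue
        b = min(int(np.searchsorted(edges, x, side="right")) - 1, n_bins - 1)
        if annotations[c.gene_id].is_transmembrane:
            n_tm[b] += 1
        else:
            n_non[b] += 1
    frac = [
        (t / (t + o)) if (t + o) > 0 else float("nan")
        for t, o in zip(n_tm, n_non)
    ]
    return pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "n_tm": n_tm,
            "n_non_tm": n_non,
            "fraction_tm": frac,
        }
    )


def annotations_to_frame(annotations: Mapping[str, TMAnnotation]) -> pd.DataFrame:
    rows = []
    for gid in sorted(annotations):
        a = annotations[gid]
        rows.append(
            {
                "gene_id": gid,
                "n_tm_segments": a.n_tm_segments,
                "segments": ";".join(f"{s}-{e}" for s, e in a.segments),
                "source": a.source,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_tm_segments", "segments", "source"])


def annotations_from_tsv(path) -> dict[str, TMAnnotation]:
    """Import precomputed annotations (gene_id, n_tm_segments[, segments])."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "n_tm_segments"} <= set(df.columns):
        raise InvalidInputError("annotation TSV must have columns gene_id, n_tm_segments")
    out: dict[str, TMAnnotation] = {}
    for r in df.itertuples():
        segs: list[tuple[int, int]] = []
        raw = getattr(r, "segments", "")
        if isinstance(raw, str) and raw:
            for part in raw.split(";"):
                s, e = part.split("-")
                segs.append((int(s), int(e)))
        out[str(r.gene_id)] = TMAnnotation(
            gene_id=str(r.gene_id), n_tm_segments=int(r.n_tm_segments),
            segments=segs, source="IMPORTED",
        )
    return out
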