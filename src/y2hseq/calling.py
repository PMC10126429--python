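"""Background-calibrated interactor calling.

A pooled selection screen against an empty bait vector measures the
self-activation / carry-over background of the prey library.  Candidate
interactors of the real bait are the genes whose bait-screen FPKM is enriched
over that baseline: a gene is accepted iff

    log2((FPKM_bait + c) / (FPKM_empty + c)) > logfc_threshold   (strictly)
    and one-sided p < p_threshold                                 (strictly)

with pseudocount ``c`` (FPKM units) keeping the log fold change finite.  The
p-value is a one-sided Fisher's exact test on assigned read counts with the
screens' mapped totals as margins — counts are the primitive observable of a
pooled screen and the design has no replicates.  No multiple-testing
correction enters the accept rule; a Benjamini-Hochberg q-value is reported
as an informational column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InconsistencyError, InvalidConfigError, InvalidInputError
from .quantify import CountTable, FPKMTable


@dataclass(frozen=True)
class CallingConfig:
    """Acceptance rule parameters (thresholds are strict inequalities)."""

    logfc_threshold: float = 1.5
    p_threshold: float = 0.05
    pseudocount: float = 0.5
    log_base: int = 2

    def validate(self) -> None:
        if self.logfc_threshold <= 0 or self.p_threshold <= 0:
            raise InvalidConfigError("thresholds must be > 0")
        if self.pseudocount <= 0:
            raise InvalidConfigError("pseudocount must be > 0")
        if self.log_base != 2:
            raise InvalidConfigError("only log base 2 is supported")


@dataclass
class InteractorCall:
    """Per-gene evidence and decision for one bait-vs-empty comparison."""

    gene_id: str
    count_bait: int
    count_empty: int
    fpkm_bait: float
    fpkm_empty: float
    logfc: float
    p_value: float
    q_value: float
    accepted: bool


def compute_logfc(fpkm_bait: float, fpkm_empty: float, config: CallingConfig) -> float:
    """log2 fold change of bait over empty FPKM, pseudocount-stabilized."""
    if fpkm_bait < 0 or fpkm_empty < 0:
        raise InvalidInputError("FPKM values must be non-negative")
    c = config.pseudocount
    return math.log2((fpkm_bait + c) / (fpkm_empty + c))


def count_test(count_bait: int, total_bait: int, count_empty: int, total_empty: int) -> float:
    """One-sided Fisher's exact test (bait proportion greater).

    2x2 table: [[count_bait, total_bait - count_bait],
                [count_empty, total_empty - count_empty]].
    """
    for c, t in ((count_bait, total_bait), (count_empty, total_empty)):
        if t <= 0:
            raise InvalidInputError("totals must be > 0")
        if not 0 <= c <= t:
            raise InvalidInputError(f"count {c} outside [0, total={t}]")
    _, p = stats.fisher_exact(
        [[count_bait, total_bait - count_bait], [count_empty, total_empty - count_empty]],
        alternative="greater",
    )
    return float(p)


def call_interactors(
    fpkm_bait: FPKMTable,
    fpkm_empty: FPKMTable,
    counts_bait: CountTable,
    counts_empty: CountTable,
    config: CallingConfig | None = None,
) -> list[InteractorCall]:
    """Call interactors for every gene identified in the bait screen.

    The "identified" set is every gene with at least one assigned bait read;
    genes absent from a screen contribute count 0 and FPKM 0 there.  Output is
    sorted by descending log fold change, ties broken by gene id.
    """
    config = config or CallingConfig()
    config.validate()
    for fpkm, counts in ((fpkm_bait, counts_bait), (fpkm_empty, counts_empty)):
        if fpkm.screen_label != counts.screen_label:
            raise InconsistencyError("FPKM and count tables are from different screens")
        if fpkm.mapped_total != counts.n_assigned:
            raise InconsistencyError(
                f"{fpkm.screen_label}: FPKM denominator {fpkm.mapped_total} != "
                f"assigned reads {counts.n_assigned}"
            )

    identified = sorted(g for g, c in counts_bait.counts.items() if c > 0)
    calls: list[InteractorCall] = []
    for gid in identified:
        cb = counts_bait.counts.get(gid, 0)
        ce = counts_empty.counts.get(gid, 0)
        fb = fpkm_bait.fpkm.get(gid, 0.0)
        fe = fpkm_empty.fpkm.get(gid, 0.0)
        logfc = compute_logfc(fb, fe, config)
        p = count_test(cb, counts_bait.n_assigned, ce, counts_empty.n_assigned)
        calls.append(
            InteractorCall(
                gene_id=gid, count_bait=cb, count_empty=ce,
                fpkm_bait=fb, fpkm_empty=fe, logfc=logfc,
                p_value=p, q_value=math.nan,
                accepted=(logfc > config.logfc_threshold) and (p < config.p_threshold),
            )
        )
    if calls:
        qs = multipletests([c.p_value for c in calls], method="fdr_bh")[1]
        for call, q in zip(calls, qs):
            call.q_value = float(q)
    calls.sort(key=lambda c: (-c.logfc, c.gene_id))
    return calls


def venn_partition(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Disjoint partition counts (only_a, shared, only_b) of two sets."""
    set_a, set_b = set(set_a), set(set_b)
    shared = len(set_a & set_b)
    return (len(set_a) - shared, shared, len(set_b) - shared)


def calls_to_frame(calls: list[InteractorCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "count_bait": [c.count_bait for c in calls],
            "count_empty": [c.count_empty for c in calls],
            "fpkm_bait": [c.fpkm_bait for c in calls],
            "fpkm_empty": [c.fpkm_empty for c in calls],
            "logfc": [c.logfc for c in calls],
            "p_value": [c.p_value for c in calls],
            "q_value": [c.q_value for c in calls],
            "accepted": [bool(c.accepted) for c in calls],
        }
    )


def calls_from_frame(df: pd.DataFrame) -> list[InteractorCall]:
    return [
        InteractorCall(
            gene_id=str(r.gene_id), count_bait=int(r.count_bait),
            count_empty=int(r.count_empty), fpkm_bait=float(r.fpkm_bait),
            fpkm_empty=float(r.fpkm_empty), logfc=float(r.logfc),
            p_value=float(r.p_value), q_value=float(r.q_value),
            accepted=bool(r.accepted),
        )
        for r in df.itertuples()
    ]
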