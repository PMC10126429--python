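"""Differential membrane-proteome analysis and Y2H integration.

Replicate label-free abundances (deletion strain vs control, three biological
replicates in the motivating design) are compared per protein with a Welch
t-test on log2 abundances; a protein is UP if log2FC > 1 and p < 0.05, DOWN
if log2FC < -1 and p < 0.05, otherwise NS (all inequalities strict).  The
down-regulated set is then intersected with the Y2H interactor set — proteins
supported by both orthogonal experiments are the high-confidence cargo
candidates of the deleted receptor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

UP, DOWN, NS = "UP", "DOWN", "NS"


@dataclass
class ProteomeRecord:
    protein_id: str
    abundances_control: tuple[float, ...]
    abundances_mutant: tuple[float, ...]
    log2fc: float
    p_value: float
    q_value: float
    regulation: str


def differential_proteins(
    table: pd.DataFrame | Sequence[tuple],
    log2fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list[ProteomeRecord]:
    """Per-protein differential abundance, mutant vs control.

    ``table`` is a DataFrame with columns ``protein_id, c1..cN, m1..mN`` or an
    iterable of ``(protein_id, control_replicates, mutant_replicates)``.
    log2FC = mean(log2 mutant) - mean(log2 control); two-sided Welch t-test on
    log2 abundances.  Proteins with any missing replicate are excluded with a
    log message; non-positive abundances are an error (log undefined).
    """
    rows: list[tuple[str, np.ndarray, np.ndarray]] = []
    if isinstance(table, pd.DataFrame):
        c_cols = sorted((c for c in table.columns if c.startswith("c") and c[1:].isdigit()),
                        key=lambda c: int(c[1:]))
        m_cols = sorted((c for c in table.columns if c.startswith("m") and c[1:].isdigit()),
                        key=lambda c: int(c[1:]))
        if "protein_id" not in table.columns or not c_cols or not m_cols:
            raise InvalidInputError("table must have protein_id, c1..cN and m1..mN columns")
        for r in table.itertuples():
            rows.append(
                (str(r.protein_id),
                 np.array([getattr(r, c) for c in c_cols], dtype=float),
                 np.array([getattr(r, c) for c in m_cols], dtype=float))
            )
    else:
        for pid, ctrl, mut in table:
            rows.append((str(pid), np.asarray(ctrl, dtype=float), np.asarray(mut, dtype=float)))

    records: list[ProteomeRecord] = []
    n_skipped = 0
    for pid, ctrl, mut in rows:
        if np.isnan(ctrl).any() or np.isnan(mut).any():
            n_skipped += 1
            logger.info("%s: missing replicate abundance; excluded", pid)
            continue
        if len(ctrl) < 2 or len(mut) < 2:
            raise InvalidInputError(f"{pid}: need >= 2 replicates per group")
        if (ctrl <= 0).any() or (mut <= 0).any():
            raise InvalidInputError(f"{pid}: abundances must be > 0 (log undefined)")
        lc, lm = np.log2(ctrl), np.log2(mut)
        log2fc = float(lm.mean() - lc.mean())
        t = stats.ttest_ind(lm, lc, equal_var=False)
        p = float(t.pvalue)
        if math.isnan(p):  # both groups constant: no evidence against the null
            p = 1.0
        if log2fc > log2fc_threshold and p < p_threshold:
            reg = UP
        elif log2fc < -log2fc_threshold and p < p_threshold:
            reg = DOWN
        else:
            reg = NS
        records.append(
            ProteomeRecord(
                protein_id=pid,
                abundances_control=tuple(float(x) for x in ctrl),
                abundances_mutant=tuple(float(x) for x in mut),
                log2fc=log2fc, p_value=p, q_value=math.nan, regulation=reg,
            )
        )
    if n_skipped:
        logger.warning("excluded %d proteins with missing replicates", n_skipped)
    if records:
        qs = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, qs):
            r.q_value = float(q)
    return records


@dataclass
class OverlapReport:
    """Intersection of the down-regulated proteome with the Y2H interactome."""

    n_overlap: int
    overlap_ids: list[str]
    transporter_fraction: float | None  # None when the overlap is empty

    def to_dict(self) -> dict:
        return {
            "n_overlap": self.n_overlap,
            "overlap_ids": self.overlap_ids,
            "transporter_fraction": self.transporter_fraction,
        }


def overlap_with_interactome(
    down_set: Iterable[str],
    interactors: Iterable[str],
    transporter_annotation: Iterable[str],
) -> OverlapReport:
    """Overlap of down-regulated proteins with interactors, and the fraction
    of that overlap annotated as transporters (identifiers must share one
    gene/protein namespace)."""
    down = set(down_set)
    inter = set(interactors)
    transporters = set(transporter_annotation)
    overlap = down & inter
    frac = (len(overlap & transporters) / len(overlap)) if overlap else None
    return OverlapReport(
        n_overlap=len(overlap), overlap_ids=sorted(overlap), transporter_fraction=frac
    )


def records_to_frame(records: list[ProteomeRecord]) -> pd.DataFrame:
    n_c = len(records[0].abundances_control) if records else 0
    n_m = len(records[0].abundances_mutant) if records else 0
    data: dict[str, list] = {"protein_id": [r.protein_id for r in records]}
    for j in range(n_c):
        data[f"c{j + 1}"] = [r.abundances_control[j] for r in records]
    for j in range(n_m):
        data[f"m{j + 1}"] = [r.abundances_mutant[j] for r in records]
    data["log2fc"] = [r.log2fc for r in records]
    data["p_value"] = [r.p_value for r in records]
    data["q_value"] = [r.q_value for r in records]
    data["regulation"] = [r.regulation for r in records]
    return pd.DataFrame(data)


def read_abundance_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise InvalidInputError("abundance TSV must have a protein_id column")
    return df
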