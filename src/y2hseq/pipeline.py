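"""End-to-end orchestration: simulate -> quantify -> call -> annotate -> enrich
-> proteome-integrate, with one config, one run directory and one seed.

Every stage writes its outputs as plain-text tables into the run directory;
rerunning with the same config and seed reproduces them byte-identically.
Stage wall-clock timings go to a separate ``timings.json`` so the report
itself stays deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .calling import CallingConfig, calls_to_frame, call_interactors, venn_partition
from .enrichment import hypergeom_enrichment, results_to_frame, write_gene_term_tsv
from .errors import InvalidConfigError, Y2HSeqError
from .proteome import (
    differential_proteins,
    overlap_with_interactome,
    records_to_frame,
)
from .quantify import assign_reads, compute_fpkm
from .simulate import (
    BAIT,
    EMPTY,
    ScreenTruth,
    SimConfig,
    generate_annotations,
    generate_library,
    simulate_proteome,
    simulate_screen,
    write_library_fasta,
)
from .tm import annotate_library, annotations_to_frame, fpkm_bin_tm_fraction

logger = logging.getLogger(__name__)

_DEFAULT_BIN_EDGES = [1.0, 10.0, 100.0, 1_000.0, 10_000.0, 100_000.0, 1_000_000.0]


@dataclass
class ProteomeSimSettings:
    """How the demo deletion-strain proteome is planted.

    A fraction of library genes is "quantified"; true interactors (cargo of
    the deleted receptor) are preferentially planted down-regulated so the
    Y2H/proteome overlap is informative.
    """

    quantified_fraction: float = 0.6
    p_down_given_interactor: float = 0.6
    p_down_background: float = 0.15
    p_up_background: float = 0.08
    planted_log2fc: float = 2.0
    replicate_cv: float = 0.10
    n_reps: int = 3


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    proteome: ProteomeSimSettings = field(default_factory=ProteomeSimSettings)
    min_seed_len: int = 20
    max_mismatches: int = 2
    tm_window: int = 19
    tm_threshold: float = 1.6
    fpkm_bin_edges: list[float] = field(default_factory=lambda: list(_DEFAULT_BIN_EDGES))
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # the global seed fixes every stage seed deterministically
        object.__setattr__(self, "sim", self.sim.replace(seed=self._stage_seed(0)))

    def _stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence(self.seed).generate_state(8)[stage] % (2**31))

    def validate(self) -> None:
        self.sim.validate()
        self.calling.validate()
        if not 0 < self.proteome.quantified_fraction <= 1:
            raise InvalidConfigError("quantified_fraction must be in (0, 1]")
        if self.proteome.n_reps < 2:
            raise InvalidConfigError("proteome n_reps must be >= 2")
        if len(self.fpkm_bin_edges) < 2 or any(
            a >= b for a, b in zip(self.fpkm_bin_edges, self.fpkm_bin_edges[1:])
        ):
            raise InvalidConfigError("fpkm_bin_edges must be strictly increasing")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimConfig.from_dict(d.pop("sim", {}))
        calling = CallingConfig(**d.pop("calling", {}))
        prot = ProteomeSimSettings(**d.pop("proteome", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"sim", "calling", "proteome"}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(sim=sim, calling=calling, proteome=prot, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Machine-readable per-stage record counts for one pipeline run."""

    config: dict
    version: str
    n_genes: int
    reads: dict
    assignment: dict
    n_identified: int
    n_accepted: int
    venn_identified_vs_empty: dict
    tm: dict
    enrichment_top_terms: list
    proteome: dict
    overlap: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_markdown(self) -> str:
        lines = [
            "# Pooled Y2H screen run report",
            "",
            f"y2hseq version {self.version}",
            "",
            f"* library genes: {self.n_genes}",
            f"* reads: bait {self.reads['BAIT']}, empty {self.reads['EMPTY']}",
        ]
        for label in (BAIT, EMPTY):
            a = self.assignment[label]
            lines.append(
                f"* {label.lower()} assignment: {a['n_assigned']} assigned, "
                f"{a['n_ambiguous']} ambiguous, {a['n_unassigned']} unassigned"
            )
        v = self.venn_identified_vs_empty
        lines += [
            f"* identified (>= 1 bait read): {self.n_identified}",
            f"* accepted interactors (logFC/p filter): {self.n_accepted}",
            f"* Venn bait-identified vs empty-detected: only bait {v['only_a']}, "
            f"shared {v['shared']}, only empty {v['only_b']}",
            f"* accepted TM / non-TM: {self.tm['n_tm']} / {self.tm['n_non_tm']}",
            f"* proteome: {self.proteome['n_quantified']} quantified, "
            f"{self.proteome['n_up']} up, {self.proteome['n_down']} down, "
            f"{self.proteome['n_ns']} unchanged",
            f"* Y2H x down-regulated overlap: {self.overlap['n_overlap']} proteins",
        ]
        return "\n".join(lines) + "\n"


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Run every stage into ``outdir`` and return the run report.

    Any stage failure is re-raised annotated with the stage name; outputs of
    completed stages remain in the run directory.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}
    config.to_yaml(outdir / "config.yaml")

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        library, truth = generate_library(config.sim)
        write_library_fasta(library, outdir / "library_cds.fasta",
                            outdir / "library_protein.fasta")
        truth.to_tsv(outdir / "truth.tsv")
        annotation, term_names = generate_annotations(
            library, truth, seed=config._stage_seed(1)
        )
        write_gene_term_tsv(annotation, outdir / "gene_terms.tsv")
        readsets = {}
        for label in (BAIT, EMPTY):
            rs = simulate_screen(library, truth, config.sim, label)
            rs.to_fastq(outdir / f"reads_{label.lower()}.fastq")
            rs.provenance_frame().to_csv(
                outdir / f"provenance_{label.lower()}.tsv", sep="\t", index=False
            )
            readsets[label] = rs
        timings[stage] = time.perf_counter() - t0

        stage = "quantify"
        t0 = time.perf_counter()
        counts, fpkm = {}, {}
        for label in (BAIT, EMPTY):
            ct = assign_reads(readsets[label], library,
                              min_seed_len=config.min_seed_len,
                              max_mismatches=config.max_mismatches)
            ct.to_tsv(outdir / f"counts_{label.lower()}.tsv")
            ft = compute_fpkm(ct, library)
            ft.to_tsv(outdir / f"fpkm_{label.lower()}.tsv")
            counts[label], fpkm[label] = ct, ft
        timings[stage] = time.perf_counter() - t0

        stage = "call"
        t0 = time.perf_counter()
        calls = call_interactors(fpkm[BAIT], fpkm[EMPTY], counts[BAIT], counts[EMPTY],
                                 config.calling)
        calls_frame = calls_to_frame(calls)
        calls_frame.to_csv(outdir / "calls.tsv", sep="\t", index=False)
        identified = {c.gene_id for c in calls}
        empty_detected = {g for g, c in counts[EMPTY].counts.items() if c > 0}
        only_a, shared, only_b = venn_partition(identified, empty_detected)
        venn = {"only_a": only_a, "shared": shared, "only_b": only_b,
                "set_a": "bait_identified", "set_b": "empty_detected"}
        _write_json(venn, outdir / "venn.json")
        accepted = {c.gene_id for c in calls if c.accepted}
        timings[stage] = time.perf_counter() - t0

        stage = "annotate-tm"
        t0 = time.perf_counter()
        proteins = {g.gene_id: g.protein_seq for g in library if g.protein_seq}
        tm_ann = annotate_library(proteins, window=config.tm_window,
                                  threshold=config.tm_threshold)
        annotations_to_frame(tm_ann).to_csv(outdir / "tm_annotations.tsv",
                                            sep="\t", index=False)
        tm_bins = fpkm_bin_tm_fraction(calls, tm_ann, config.fpkm_bin_edges)
        tm_bins.to_csv(outdir / "tm_bins.tsv", sep="\t", index=False)
        n_tm = sum(1 for g in accepted if tm_ann[g].is_transmembrane)
        timings[stage] = time.perf_counter() - t0

        stage = "enrich"
        t0 = time.perf_counter()
        enr = []
        if accepted:
            enr = hypergeom_enrichment(accepted, annotation, identified, term_names)
            results_to_frame(enr).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "proteome"
        t0 = time.perf_counter()
        rng = np.random.default_rng(config._stage_seed(2))
        gene_ids = [g.gene_id for g in library]
        n_quant = max(1, int(round(config.proteome.quantified_fraction * len(gene_ids))))
        quantified = sorted(rng.choice(gene_ids, size=n_quant, replace=False).tolist())
        interactors = truth.interactors
        ps = config.proteome
        down_ids, up_ids = set(), set()
        for pid in quantified:
            r = rng.random()
            if pid in interactors:
                if r < ps.p_down_given_interactor:
                    down_ids.add(pid)
            elif r < ps.p_down_background:
                down_ids.add(pid)
            elif r < ps.p_down_background + ps.p_up_background:
                up_ids.add(pid)
        abundance, prot_truth = simulate_proteome(
            quantified, seed=config._stage_seed(3), n_reps=ps.n_reps,
            up_ids=up_ids, down_ids=down_ids,
            planted_log2fc=ps.planted_log2fc, replicate_cv=ps.replicate_cv,
        )
        abundance.to_csv(outdir / "proteome_abundance.tsv", sep="\t", index=False)
        prot_truth.to_csv(outdir / "proteome_truth.tsv", sep="\t", index=False)
        records = differential_proteins(abundance)
        records_to_frame(records).to_csv(outdir / "proteome_records.tsv",
                                         sep="\t", index=False)
        down_called = {r.protein_id for r in records if r.regulation == "DOWN"}
        transporter_genes = annotation.get("T:0001", set())
        overlap = overlap_with_interactome(down_called, accepted, transporter_genes)
        _write_json(overlap.to_dict(), outdir / "overlap.json")
        timings[stage] = time.perf_counter() - t0
    except Y2HSeqError as err:
        raise Y2HSeqError(f"pipeline stage '{stage}' failed: {err}") from err

    stage = "report"
    n_up = sum(1 for r in records if r.regulation == "UP")
    n_down = sum(1 for r in records if r.regulation == "DOWN")
    report = RunReport(
        config=config.to_dict(),
        version=__version__,
        n_genes=len(library),
        reads={label: len(readsets[label]) for label in (BAIT, EMPTY)},
        assignment={
            label: {
                "n_assigned": counts[label].n_assigned,
                "n_ambiguous": counts[label].n_ambiguous,
                "n_unassigned": counts[label].n_unassigned,
            }
            for label in (BAIT, EMPTY)
        },
        n_identified=len(calls),
        n_accepted=len(accepted),
        venn_identified_vs_empty=venn,
        tm={"n_tm": n_tm, "n_non_tm": len(accepted) - n_tm},
        enrichment_top_terms=[
            {"term_id": r.term_id, "term_name": r.term_name, "p_value": r.p_value,
             "q_value": r.q_value}
            for r in enr[:5]
        ],
        proteome={
            "n_quantified": len(records),
            "n_up": n_up,
            "n_down": n_down,
            "n_ns": len(records) - n_up - n_down,
        },
        overlap=overlap.to_dict(),
    )
    _write_json(report.to_dict(), outdir / "report.json")
    (outdir / "report.md").write_text(report.to_markdown())
    _write_json(timings, outdir / "timings.json")
    return report


def evaluate_against_truth(calls, truth: ScreenTruth) -> dict:
    """Benchmark calls against simulator ground truth.

    Sensitivity is computed over *pure* interactors (interactor and not
    self-activator): a prey that both interacts and self-activates is
    structurally invisible to background subtraction, since it is enriched in
    the empty screen too.  FDR counts accepted genes that are not true
    interactors.  Also reports the fraction of pure self-activators rejected.
    """
    accepted = {c.gene_id for c in calls if c.accepted}
    pure_interactors = truth.pure_interactors
    interactors = truth.interactors
    pure_sa = truth.pure_self_activators
    tp = len(accepted & pure_interactors)
    sensitivity = tp / len(pure_interactors) if pure_interactors else float("nan")
    fp = len(accepted - interactors)
    fdr = fp / len(accepted) if accepted else 0.0
    sa_rejected = (
        1.0 - len(accepted & pure_sa) / len(pure_sa) if pure_sa else float("nan")
    )
    return {
        "n_accepted": len(accepted),
        "sensitivity": sensitivity,
        "fdr": fdr,
        "self_activator_rejection": sa_rejected,
    }
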