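"""End-to-end orchestration: simulate -> stitch -> quantify -> diffexpr ->
classify -> evidence.

Each stage reads from / writes into a shared ``PipelineState`` and persists
its outputs as TSV/FASTA under the run directory, so any prefix of the stage
list is runnable and every run is reproducible from its logged config and
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import diffexpr as de
from . import pathway_evidence as pe
from . import quantify as qt
from . import reference_builder as rb
from . import residue_classifier as rc
from . import synthetic_data as sd
from .errors import StageError
from .io import RunConfig, write_fasta, write_tsv

log = logging.getLogger("kranzless")

STAGE_ORDER = ("simulate", "stitch", "quantify", "diffexpr", "classify", "evidence")

# Hordeum-like diagnostic pattern: one C4-candidate copy among five.
DEFAULT_PEPC_SPEC = [("synthTriticum", 5, ["R", "S", "R", "R", "R"])]


@dataclass
class PipelineState:
    config: RunConfig
    records: list = None
    truth: sd.SimTruth = None
    events: list = None
    counts: qt.CountMatrix = None
    rpkm: qt.RpkmMatrix = None
    units: pd.DataFrame = None
    subgenome: qt.SubgenomeTable = None
    contrasts: dict = field(default_factory=dict)
    diff_results: pd.DataFrame = None
    ppc_calls: list = None
    ppc_summary: rc.FamilySummary = None
    verdict: pe.PathwayVerdict = None


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    sim = sd.SimConfig(**{**cfg.simulate, "seed": cfg.simulate.get("seed", cfg.seed)})
    records, truth = sd.simulate_reference(sim)
    overlap = cfg.stitch.get("split_overlap_nt", 30)
    records, truth = sd.split_transcripts(
        records, sim.n_split_transcripts, overlap, seed=sim.seed + 1, truth=truth
    )
    state.records, state.truth = records, truth
    state.sim_config = sim
    out = _outdir(cfg)
    write_fasta(records, out / "reference.fasta")
    write_tsv(
        pd.DataFrame(truth.split_pairs, columns=["frag_a", "frag_b", "parent_id"]),
        out / "truth_split_pairs.tsv",
    )
    write_tsv(pd.DataFrame({"transcript_id": sorted(truth.de_transcripts)}),
              out / "truth_grain_up.tsv")
    log.info("simulate: %d transcripts, %d split pairs",
             len(records), len(truth.split_pairs))


def stage_stitch(state: PipelineState) -> None:
    cfg = state.config
    candidates = rb.find_split_candidates(
        state.records,
        min_overlap=cfg.stitch.get("min_overlap", rb.MIN_OVERLAP_DEFAULT),
        min_identity=cfg.stitch.get("min_identity", rb.MIN_IDENTITY_DEFAULT),
        use_guides=cfg.stitch.get("use_guides", False),
    )
    modified, events = rb.stitch_candidates(state.records, candidates)
    state.records, state.events = modified, events
    out = _outdir(cfg)
    write_fasta(modified, out / "modified_reference.fasta")
    write_tsv(
        pd.DataFrame([vars(e) for e in events]),
        out / "stitch_events.tsv",
    )
    log.info("stitch: %d events, reference %d records", len(events), len(modified))


def stage_quantify(state: PipelineState) -> None:
    cfg = state.config
    sim = getattr(state, "sim_config", None) or sd.SimConfig(**cfg.simulate)
    counts = sd.simulate_counts(state.records, sim, state.truth,
                                seed=cfg.seed + 2)
    units = qt.read_units(counts)
    rpkm = qt.compute_rpkm(units, counts.lengths)
    annotation = pd.DataFrame(
        {
            "transcript_id": [r.id for r in state.records],
            "gene": [r.gene for r in state.records],
            "subgenome": [r.subgenome for r in state.records],
        }
    )
    subgenome = qt.subgenome_aggregate(rpkm, annotation)
    tissue_means = subgenome.tissue_means(counts.sample_meta)
    grain = cfg.quantify.get("grain_tissue", sim.tissues[0])
    leaf = cfg.quantify.get("leaf_tissue", sim.tissues[-1])
    contrasts = {}
    floor = cfg.quantify.get("floor", 0.01)
    for gene in tissue_means.index:
        contrasts[gene] = qt.fold_change(
            float(tissue_means.loc[gene, grain]),
            float(tissue_means.loc[gene, leaf]),
            floor=floor, gene=gene,
            numerator_tissue=grain, denominator_tissue=leaf,
        )
    state.counts, state.units, state.rpkm = counts, units, rpkm
    state.subgenome, state.contrasts = subgenome, contrasts
    out = _outdir(cfg)
    write_tsv(counts.to_long(), out / "counts.tsv")
    write_tsv(counts.sample_meta.reset_index(), out / "sample_meta.tsv")
    write_tsv(rpkm.values.reset_index(names="transcript_id"), out / "rpkm.tsv")
    write_tsv(
        pd.DataFrame(
            [
                {
                    "gene": c.gene, "mean_grain": c.mean_num, "mean_leaf": c.mean_den,
                    "fold": c.fold, "fold_rounded": c.fold_rounded,
                    "direction": c.direction,
                }
                for c in contrasts.values()
            ]
        ),
        out / "contrasts.tsv",
    )
    log.info("quantify: %d transcripts x %d samples", *rpkm.values.shape)


def stage_diffexpr(state: PipelineState) -> None:
    cfg = state.config
    meta = state.counts.sample_meta
    tissue_a = cfg.diffexpr.get("group_a", meta["tissue"].iloc[0])
    tissue_b = cfg.diffexpr.get("group_b", meta["tissue"].iloc[-1])
    samples_a = meta.index[meta["tissue"] == tissue_a].tolist()
    samples_b = meta.index[meta["tissue"] == tissue_b].tolist()
    params = de.DiffParams(
        alpha=cfg.diffexpr.get("alpha", 0.01),
        presence_floor=cfg.diffexpr.get("presence_floor", 0.5),
    )
    results = de.run_two_group(state.rpkm.values, state.units,
                               samples_a, samples_b, params)
    state.diff_results = results
    write_tsv(results.reset_index(), _outdir(cfg) / "diffexpr.tsv")
    log.info("diffexpr %s vs %s: %d significant", tissue_a, tissue_b,
             int(results["significant"].sum()))


def stage_classify(state: PipelineState) -> None:
    cfg = state.config
    if "fasta" in cfg.classify:
        from .io import read_fasta

        proteins, truth = read_fasta(cfg.classify["fasta"]), None
    else:
        family_spec = cfg.classify.get("family_spec", DEFAULT_PEPC_SPEC)
        proteins, truth = sd.simulate_pepc_family(family_spec, seed=cfg.seed + 3)
    calls, summary = rc.classify_family(proteins)
    state.ppc_calls, state.ppc_summary = calls, summary
    state.ppc_truth = truth
    write_tsv(rc.calls_to_frame(calls), _outdir(cfg) / "ppc_calls.tsv")
    log.info("classify: %d copies, %d C3, %d C4-candidate",
             summary.n_copies, summary.n_C3, summary.n_C4)


def stage_evidence(state: PipelineState) -> None:
    cfg = state.config
    sim = getattr(state, "sim_config", None) or sd.SimConfig(**cfg.simulate)
    annotations = []
    role_map = {r.gene: r for r in pe.builtin_roles()}
    targeting_word = {"cytosolic": "cyt", "mitochondrial": "mt", "chloroplastic": "cp"}
    arm_by_gene = {r.gene: r.arm for r in state.records if r.gene in role_map}
    for gene in sim.c4_gene_set:
        role = role_map.get(gene)
        if role is None:
            continue
        compartment = sorted(role.c4_compartments)[0]
        arm = arm_by_gene.get(gene, "3L")
        locus = f"{arm[0]}{''.join(sim.subgenomes)}{arm[-1]}"
        annotations.append(
            pe.GeneCopyAnnotation(gene=gene, locus=locus,
                                  targeting=targeting_word[compartment])
        )
    verdict = pe.assemble_evidence(
        annotations, state.contrasts, state.ppc_calls,
        pe.EvidenceConfig(
            fold_threshold=cfg.evidence.get("fold_threshold", 2.0),
            rpkm_floor=cfg.evidence.get("rpkm_floor", 1.0),
        ),
    )
    state.verdict = verdict
    out = _outdir(cfg)
    (out / "verdict.txt").write_text(pe.verdict_summary(verdict) + "\n")
    write_tsv(
        pd.DataFrame(
            [
                {
                    "gene": ev.gene, "grain_up": ev.grain_up,
                    "fold": ev.contrast.fold if ev.contrast else float("nan"),
                    "subgenomes": "".join(ev.subgenomes),
                    "gaps": "; ".join(ev.gaps),
                }
                for ev in verdict.evidence
            ]
        ),
        out / "evidence.tsv",
    )
    log.info("evidence: %s", "positive" if verdict.positive else
             f"negative (gaps: {sorted(verdict.gaps)})")


_STAGES = {
    "simulate": stage_simulate,
    "stitch": stage_stitch,
    "quantify": stage_quantify,
    "diffexpr": stage_diffexpr,
    "classify": stage_classify,
    "evidence": stage_evidence,
}


def run_pipeline(config: RunConfig) -> PipelineState:
    """Run the configured stages in canonical order; halt on first failure."""
    state = PipelineState(config=config)
    out = _outdir(config)
    with open(out / "run_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        try:
            _STAGES[stage](state)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
    return state
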