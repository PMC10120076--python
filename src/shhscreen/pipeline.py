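"""End-to-end pipeline: simulate (optional) -> score screens -> score assay
-> dosage expression -> prioritize, with a machine-readable run manifest.

Each stage failure raises :class:`~shhscreen.errors.PipelineError` naming
the stage.  Outputs are headered TSVs with stable column order; a run with
the same config and seed reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .assay_stats import DifferentiationAssay
from .dosage import DosageExperiment, detectable, detection_filter, fpkm, gene_lengths, tpm
from .errors import PipelineError, ShhScreenError
from .io import (
    PipelineConfig,
    file_digest,
    read_counts_tsv,
    read_gene_models,
    read_ortholog_map_tsv,
    read_sample_meta_tsv,
    write_gff3,
    write_tsv,
)
from .plate_screen import (
    LuciferaseScreen,
    ScreenThresholds,
    cross_screen_concordance,
    score_screen_values,
)
from .prioritize import ModelSegments, build_candidate_report, load_model_segments, rank_candidates
from .simulate import CountSimConfig, PlateSimConfig, simulate_counts, simulate_plates

logger = logging.getLogger(__name__)

SIM_DEFAULTS = dict(
    n_cdnas=24,
    replicates_per_cdna=8,
    n_inhibitors=3,
    inhibitor_effect=0.6,
    n_activators=2,
    activator_effect=1.6,
    n_genes=200,
    n_trisomic_genes=40,
    dispersion=0.05,
    library_size=1e6,
)


@dataclass
class PipelineReport:
    outdir: Path
    candidates: pd.DataFrame
    manifest: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ShhScreenError as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


def _simulate_inputs(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = dict(SIM_DEFAULTS, **(cfg.simulate or {}))
    count_cfg = CountSimConfig(
        n_genes=int(sim["n_genes"]),
        n_trisomic_genes=int(sim["n_trisomic_genes"]),
        dispersion=float(sim["dispersion"]),
        library_size=float(sim["library_size"]),
        transchromosomic=cfg.transchromosomic,
        seed=cfg.seed + 1,
    )
    counts = simulate_counts(count_cfg)

    trisomic = counts.truth.loc[counts.truth["copies"] == 3, "gene_id"].tolist()
    disomic = counts.truth.loc[counts.truth["copies"] == 2, "gene_id"].tolist()
    n_inh, n_act = int(sim["n_inhibitors"]), int(sim["n_activators"])
    n_cdnas = int(sim["n_cdnas"])
    inhibitors = trisomic[:n_inh]
    activators = disomic[:n_act]
    filler_n = n_cdnas - n_inh - n_act
    filler = (trisomic[n_inh:] + disomic[n_act:])[:filler_n]
    cdnas = inhibitors + activators + filler
    effects = {g: float(sim["inhibitor_effect"]) for g in inhibitors}
    effects |= {g: float(sim["activator_effect"]) for g in activators}

    plates = {}
    for i, screen in enumerate(("Shh-LIGHT2", "SmoA1-LIGHT", "C3H10T1/2")):
        plate_cfg = PlateSimConfig(
            n_cdnas=len(cdnas),
            cdna_names=tuple(cdnas),
            replicates_per_cdna=int(sim["replicates_per_cdna"]),
            control_label=cfg.control_label,
            effect_map=effects,
            seed=cfg.seed + 10 + i,
        )
        plates[screen] = simulate_plates(plate_cfg)

    # persist simulated inputs so the run is auditable
    simdir = outdir / "simulated"
    simdir.mkdir(exist_ok=True)
    for screen, df in plates.items():
        df.to_csv(simdir / f"plates_{screen.replace('/', '-')}.csv", index=False)
    write_tsv(counts.counts.reset_index(), simdir / "counts.tsv")
    write_tsv(counts.samples, simdir / "samples.tsv")
    write_tsv(counts.truth, simdir / "truth.tsv")
    write_gff3(counts.gene_models, simdir / "genes.gff3")
    if counts.ortholog_map is not None:
        write_tsv(counts.ortholog_map, simdir / "orthologs.tsv")

    models = _default_models(counts)
    return dict(plates=plates, counts=counts, models=models, cdnas=cdnas,
                inhibitors=inhibitors, activators=activators)


def _default_models(counts) -> list[ModelSegments]:
    """Synthetic trisomic-segment definitions derived from the simulated
    gene layout: one model trisomic for the whole segment, one carrying a
    deletion of its distal third."""
    tri = counts.truth[counts.truth["chromosome"] == "chrTri"]
    if tri.empty:
        return []
    mouse_models = {m.gene_id: m for m in counts.gene_models}
    starts = [mouse_models[g].start for g in tri["gene_id"]]
    ends = [mouse_models[g].end for g in tri["gene_id"]]
    lo, hi = min(starts), max(ends) + 1
    cut = lo + 2 * (hi - lo) // 3
    return [
        ModelSegments(name="TsFull", segments=[("chrTri", lo, hi)]),
        ModelSegments(name="TsDel", segments=[("chrTri", lo, hi)],
                      deletions=[("chrTri", cut, hi)]),
    ]


def _load_inputs(cfg: PipelineConfig) -> dict:
    plates = {
        Path(p).stem: pd.read_csv(p) for p in cfg.plates_files
    }
    counts = None
    if cfg.counts_file:
        counts_df = read_counts_tsv(cfg.counts_file)
        samples = read_sample_meta_tsv(cfg.samples_file)
        genes = read_gene_models(cfg.genes_file) if cfg.genes_file else None
        orthologs = read_ortholog_map_tsv(cfg.orthologs_file) if cfg.orthologs_file else None
        counts = dict(counts=counts_df, samples=samples, gene_models=genes, ortholog_map=orthologs)
    models = load_model_segments(cfg.models_file) if cfg.models_file else []
    assay = pd.read_csv(cfg.assay_file) if cfg.assay_file else None
    return dict(plates=plates, counts=counts, models=models, assay=assay)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full pipeline under one configuration.

    With a ``simulate`` block, inputs are generated (and written under
    ``outdir/simulated``) before scoring; otherwise the configured input
    files are read.  Returns a :class:`PipelineReport`; the JSON manifest
    (seeds, thresholds, versions, output digests) is written alongside the
    TSVs.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = ScreenThresholds(strong_z=cfg.strong_z, weak_z=cfg.weak_z)

    simulated = cfg.simulate is not None
    if simulated:
        inputs = _stage("simulate")(_simulate_inputs)(cfg, outdir)
    else:
        inputs = _stage("load")(_load_inputs)(cfg)

    # --- score screens -----------------------------------------------------
    plate_tables = inputs["plates"]
    screen_names = list(plate_tables)
    luc_names = screen_names[:2]
    z_tables = {}
    results = {}
    for name in luc_names:
        screen = LuciferaseScreen(
            plate_tables[name], control=cfg.control_label,
            min_wells=cfg.min_wells, name=name,
        )
        res = _stage("score-screen")(screen.fit)(thresholds)
        results[name] = res
        z_tables[name] = res.scores
        res.to_tsv(outdir / f"screen_{_safe(name)}.tsv")

    concordance = None
    if len(luc_names) == 2:
        concordance = _stage("score-screen")(cross_screen_concordance)(
            z_tables[luc_names[0]], z_tables[luc_names[1]], thresholds
        )
        write_tsv(concordance.reset_index(), outdir / "concordance.tsv")

    # --- secondary assay ----------------------------------------------------
    assay_df = None
    if simulated and len(screen_names) > 2:
        df = plate_tables[screen_names[2]]
        assay_df = df.assign(value=df["fluc"] / df["rluc"])[["plate", "cdna", "value"]]
    elif inputs.get("assay") is not None:
        assay_df = inputs["assay"]
    if assay_df is not None:
        assay = DifferentiationAssay(assay_df, control=cfg.control_label)
        assay_res = _stage("score-assay")(assay.fit)(cfg.alpha)
        assay_res.to_tsv(outdir / "assay.tsv")
        assay_scores, _ = _stage("score-assay")(score_screen_values)(
            assay_df, "value", control=cfg.control_label,
            min_wells=cfg.min_wells, thresholds=thresholds,
        )
        z_tables["C3H10T1/2"] = assay_scores

    # --- dosage expression --------------------------------------------------
    excluded: list[str] = []
    positions = None
    dosage_res = None
    counts_in = inputs.get("counts")
    if counts_in is not None:
        if simulated:
            experiment = DosageExperiment.from_simulation(counts_in)
            counts_df = counts_in.counts
            genotype = counts_in.genotype
            gene_models = counts_in.gene_models
        else:
            gene_models = counts_in["gene_models"]
            trisomic = None
            experiment = DosageExperiment(
                counts=counts_in["counts"],
                samples=counts_in["samples"],
                gene_models=gene_models,
                ortholog_map=counts_in["ortholog_map"],
                trisomic_genes=trisomic,
                transchromosomic=cfg.transchromosomic,
            )
            counts_df = counts_in["counts"]
            genotype = counts_in["samples"].set_index("sample")["genotype"]
        dosage_res = _stage("dosage")(experiment.fit)(
            bin_lo=cfg.bin_lo, bin_hi=cfg.bin_hi
        )
        dosage_res.to_tsv(outdir / "dosage.tsv")
        write_tsv(
            dosage_res.bin_counts.rename_axis("dosage_bin").reset_index(name="n_genes"),
            outdir / "dosage_bins.tsv",
        )

        # expression evidence for the detection filter
        cdnas = list(z_tables[luc_names[0]].index)
        lengths = gene_lengths(gene_models)
        common = counts_df.index.intersection(lengths.index)
        sub = counts_df.loc[common]
        gl = lengths.reindex(common)
        present = [g for g in cdnas if g in common]
        totals = sub.sum(axis=0)
        fpkm_mat = pd.DataFrame(
            fpkm(sub, gl.to_numpy()[:, None], totals.to_numpy()[None, :]),
            index=sub.index, columns=sub.columns,
        )
        tpm_mat = pd.DataFrame(
            {s: tpm(sub[s], gl) for s in sub.columns}, index=sub.index
        )
        det = detectable(counts_df, genotype)
        evidence = pd.DataFrame(
            {
                "detected_in_rnaseq": [bool(det[g]) for g in present],
                "fpkm_values": [list(fpkm_mat.loc[g]) for g in present],
                "tpm_values": [list(tpm_mat.loc[g]) for g in present],
            },
            index=pd.Index(present, name="gene_id"),
        )
        excluded = _stage("dosage")(detection_filter)(
            evidence, fpkm_cut=cfg.fpkm_cut, tpm_cut=cfg.tpm_cut
        )
        write_tsv(pd.DataFrame({"gene_id": excluded}), outdir / "excluded_genes.tsv")
        positions = pd.DataFrame(
            {
                "chromosome": [m.chromosome for m in gene_models],
                "pos": [m.start for m in gene_models],
            },
            index=pd.Index([m.gene_id for m in gene_models], name="gene_id"),
        )

    # --- prioritize ---------------------------------------------------------
    report = _stage("prioritize")(build_candidate_report)(
        z_tables,
        positions=positions,
        models=inputs.get("models", []),
        excluded_genes=excluded,
        concordance=concordance,
        weak_z=cfg.weak_z,
    )
    ranked_inh = rank_candidates(report, mode="inhibitors")
    ranked_act = rank_candidates(report, mode="activators")
    write_tsv(report.reset_index(), outdir / "candidate_report.tsv")
    write_tsv(ranked_inh.reset_index(), outdir / "ranked_inhibitors.tsv")
    write_tsv(ranked_act.reset_index(), outdir / "ranked_activators.tsv")

    manifest = {
        "package": "shhscreen",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "outputs": {
            p.name: file_digest(p) for p in sorted(outdir.glob("*.tsv"))
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineReport(outdir=outdir, candidates=ranked_inh, manifest=manifest)


def _safe(name: str) -> str:
    return name.replace("/", "-").replace(" ", "_")
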