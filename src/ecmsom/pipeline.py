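"""End-to-end orchestration of the analysis pipeline.

``run_all`` executes simulate -> phases -> MCR-ALS -> XANES ->
pyrolysis -> differential expression -> response types -> permutation
test in order, writes every stage's artifacts under an output
directory, and records a manifest (seeds, config hash, package
versions, stage outputs). Any stage failure aborts with the stage name
and cause; artifacts written by earlier stages are retained.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .errors import EcmsomError
from .expression import select_onset_genes, test_pairwise, test_time_course
from .mcr import fit_mcr, select_components
from .phases import detect_phases
from .pyrolysis import ox_c3g_table
from .response_types import (
    TRANSITIONS,
    build_hierarchy,
    classify_profiles,
    cluster_genes,
    count_types,
    permutation_test,
)
from .synthetic import (
    SimDesign,
    default_templates,
    make_spectral_truth,
    simulate_chemistry,
    simulate_counts,
    simulate_markers,
    simulate_pistar_areas,
    simulate_preedge,
    simulate_spectra,
    template_truth_frame,
)
from .xanes import compare_centroids, fit_preedge, n_speciation, pca_ordination

__all__ = ["run_all", "StageFailure"]


class StageFailure(EcmsomError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__
    return {"ecmsom": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__}


def run_all(config: PipelineConfig, out_dir, simulate: bool = True,
            inputs: dict | None = None) -> dict:
    """Run the full pipeline and return the manifest dictionary.

    With ``simulate=True`` every input is generated from the config's
    seed; otherwise ``inputs`` must map the keys ``chemistry``,
    ``counts``, ``meta``, ``annotations``, ``spectra``, ``markers`` to
    existing file paths (pre-edge and pi* inputs are always simulated in
    this desk-scale build).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "config_hash": config.content_hash(),
                      "versions": _versions(), "stages": {}}
    stage = "simulate"
    try:
        if simulate:
            design = SimDesign(species_label=config.species, seed=config.seed)
            chem = simulate_chemistry(design)
            templates = default_templates(
                n_per_pattern=config.n_per_pattern, n_null=config.n_null,
                seed=config.seed)
            counts, meta = simulate_counts(design, templates)
            annot = (template_truth_frame(templates)
                     .reset_index()[["gene_id", "category_path"]])
            truth = make_spectral_truth(seed=config.seed)
            spectra = simulate_spectra(truth, seed=config.seed)
            markers = simulate_markers(seed=config.seed)
            io.write_chemistry(chem, out / "chemistry.csv")
            io.write_counts(counts, out / "counts.tsv")
            io.write_meta(meta, out / "meta.tsv")
            io.write_annotations(annot, out / "annotations.tsv")
            io.write_spectra(spectra, out / "spectra.csv")
            io.write_markers(markers, out / "markers.tsv")
            io.write_json({"templates": template_truth_frame(templates)
                           .reset_index().to_dict(orient="list")},
                          out / "ground_truth.json")
            manifest["stages"]["simulate"] = {
                "outputs": ["chemistry.csv", "counts.tsv", "meta.tsv",
                            "annotations.tsv", "spectra.csv", "markers.tsv",
                            "ground_truth.json"]}
        else:
            required = {"chemistry", "counts", "meta", "annotations",
                        "spectra", "markers"}
            inputs = inputs or {}
            for key in sorted(required):
                if key not in inputs or not Path(inputs[key]).exists():
                    raise FileNotFoundError(
                        f"required input {key!r} missing "
                        f"({inputs.get(key, '<unset>')})")
            chem = io.read_chemistry(inputs["chemistry"])
            counts = io.read_counts(inputs["counts"])
            meta = io.read_meta(inputs["meta"])
            annot = io.read_annotations(inputs["annotations"])
            spectra = io.read_spectra(inputs["spectra"])
            markers = io.read_markers(inputs["markers"])
            manifest["stages"]["simulate"] = {"outputs": [], "loaded": True}

        stage = "phases"
        assignment = detect_phases(
            chem, glucose_threshold=config.glucose_threshold,
            ammonium_threshold=config.ammonium_threshold,
            pcd_lag=config.pcd_lag)
        io.write_json(assignment.to_dict(), out / "phases.json")
        manifest["stages"]["phases"] = {"outputs": ["phases.json"],
                                        "times": list(assignment.times)}

        stage = "mcr"
        selection = select_components(
            spectra, k_max=config.k_max, ev_threshold=config.ev_threshold,
            tol=config.mcr_tol, max_iter=config.mcr_max_iter,
            n_restarts=config.mcr_restarts, seed=config.seed)
        fit = fit_mcr(spectra, selection.k, tol=config.mcr_tol,
                      max_iter=config.mcr_max_iter,
                      n_restarts=config.mcr_restarts, seed=config.seed)
        pd.DataFrame(fit.C, index=list(spectra.sample_ids),
                     columns=[f"C{i+1}" for i in range(fit.k)]).to_csv(
            out / "mcr_concentrations.csv")
        pd.DataFrame(fit.S, index=spectra.axis,
                     columns=[f"C{i+1}" for i in range(fit.k)]).to_csv(
            out / "mcr_spectra.csv", index_label="axis")
        io.write_json({"k": fit.k, "explained_variance": fit.explained_variance,
                       "converged": fit.converged, "n_iter": fit.n_iter,
                       "reached_threshold": selection.reached_threshold,
                       "ev_by_k": selection.ev_by_k},
                      out / "mcr.json")
        manifest["stages"]["mcr"] = {
            "outputs": ["mcr.json", "mcr_concentrations.csv", "mcr_spectra.csv"],
            "k": fit.k, "explained_variance": fit.explained_variance}

        stage = "xanes"
        # pre-edge series: control plus one spectrum per phase; the ferrous
        # pulse at t2 follows the Fenton-archetype species, a flat ferric
        # course the other
        ferrous_course = ([0.05, 0.25, 0.75, 0.15, 0.10]
                          if not config.species.lower().startswith("lacc")
                          else [0.05, 0.08, 0.10, 0.08, 0.06])
        sample_tags = ["SOMt0", "t1", "t2", "t3", "t4"]
        centroid_groups = []
        preedge_rows = []
        for i, (tag, f) in enumerate(zip(sample_tags, ferrous_course)):
            group = []
            for rep in range(2):
                e, y = simulate_preedge(
                    f, baseline=(0.02, 0.002),
                    seed=config.seed + 13 * i + rep)
                res = fit_preedge(e, y, window=config.preedge_window)
                group.append(res.centroid)
                preedge_rows.append({"sample": f"{tag}_r{rep+1}",
                                     "centroid": res.centroid,
                                     "ferrous_fraction": res.ferrous_fraction,
                                     "integrated_area": res.integrated_area})
            centroid_groups.append(group)
        f_stat, p_anova = compare_centroids(*centroid_groups)
        areas = simulate_pistar_areas(seed=config.seed)
        abund = n_speciation(areas)
        scores, loadings, evr = pca_ordination(abund)
        io.write_json({"preedge": preedge_rows,
                       "anova": {"F": f_stat, "p": p_anova},
                       "pistar_abundances": abund.reset_index().to_dict(orient="list"),
                       "pca_variance_ratio": list(evr)},
                      out / "xanes.json")
        manifest["stages"]["xanes"] = {"outputs": ["xanes.json"],
                                       "anova_p": p_anova}

        stage = "oxc3g"
        ratios = ox_c3g_table(markers, toc_correction=config.toc_correction)
        ratios.to_csv(out / "oxc3g.tsv", sep="\t")
        manifest["stages"]["oxc3g"] = {"outputs": ["oxc3g.tsv"]}

        stage = "expression"
        tc = test_time_course(counts, meta, min_dispersion=config.min_dispersion,
                              alpha_cutoff=config.alpha)
        pw21 = test_pairwise(counts, meta, "t2", "t1",
                             min_dispersion=config.min_dispersion)
        onset = select_onset_genes(
            pw21, tc["mean_t2"], top_quantile=config.top_quantile,
            min_fold=config.min_fold, alpha=config.alpha)
        tc.to_csv(out / "time_course.tsv", sep="\t")
        pw21.to_csv(out / "pairwise_t2_t1.tsv", sep="\t")
        io.write_json({"onset_genes": sorted(onset)}, out / "onset.json")
        manifest["stages"]["expression"] = {
            "outputs": ["time_course.tsv", "pairwise_t2_t1.tsv", "onset.json"],
            "n_time_degs": int(tc["time_deg"].sum()),
            "n_onset": len(onset)}

        stage = "response_types"
        hierarchy = build_hierarchy(annot)
        pairwise = {}
        labels = sorted(meta["time_point"].unique())
        for trans, (tx, tref) in zip(TRANSITIONS,
                                     zip(labels[1:], labels[:-1])):
            pairwise[trans] = test_pairwise(
                counts, meta, tx, tref, min_dispersion=config.min_dispersion)
        profiles = classify_profiles(pairwise, config.fold_threshold,
                                     config.alpha)
        annotated_degs = [g for g in tc.index[tc["time_deg"]]
                          if g in hierarchy.gene_to_node]
        mean_cols = [c for c in tc.columns if c.startswith("mean_")]
        log_prof = np.log2(tc.loc[annotated_degs, mean_cols] + 1.0)
        clusters = cluster_genes(log_prof, hierarchy, config.corr_threshold)
        per_gene = profiles.join(clusters, how="left")
        per_gene.to_csv(out / "response_profiles.tsv", sep="\t")
        counts_by_type, n_types = count_types(profiles.loc[annotated_degs])
        io.write_json({"counts": counts_by_type.to_dict(),
                       "n_distinct_types": n_types},
                      out / "response_types.json")
        manifest["stages"]["response_types"] = {
            "outputs": ["response_profiles.tsv", "response_types.json"],
            "n_distinct_types": n_types}

        stage = "permtest"
        perm = permutation_test(
            counts, meta, hierarchy, B=config.permutation_B, seed=config.seed,
            fold_threshold=config.fold_threshold, alpha=config.alpha,
            min_dispersion=config.min_dispersion)
        perm.table.to_csv(out / "permutation.tsv", sep="\t")
        manifest["stages"]["permtest"] = {
            "outputs": ["permutation.tsv"], "B": perm.B,
            "n_significant": int((perm.table["p_emp"] < 0.05)
                                 [perm.table["observed_nonzero"]].sum())}
    except Exception as exc:                       # noqa: BLE001 - re-raise tagged
        io.write_json(manifest, out / "manifest.json")
        raise StageFailure(stage, exc) from exc

    io.write_json(manifest, out / "manifest.json")
    return manifest
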