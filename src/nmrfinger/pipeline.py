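"""End-to-end study orchestration.

Runs the three fingerprinting experiments — response prediction at
baseline, paired baseline vs 12-week treatment-effect profiling, and the
infliximab vs etanercept contrast among responders — over a directory of
spectra plus a metadata table, producing a self-contained, reproducible
report directory (JSON summary, tables, config echo, optional figures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as annotate_mod
from . import gaselect, plsda, plsreg, plots
from .io import read_spectra_dir
from .preprocess import PreprocessParams, preprocess_spectra
from .simulate import default_library

COMPARISONS = ("response_at_baseline", "baseline_vs_12week", "drug_contrast")
DISEASES = ("RA", "PsA")
DRUGS = ("infliximab", "etanercept")
TIMEPOINTS = ("baseline", "week12")

REQUIRED_COLUMNS = ("sample_id", "subject_id", "disease", "drug", "timepoint",
                    "responder")


@dataclass(frozen=True)
class StudyDesign:
    """Which comparison to run and on which slice of the cohort."""

    comparison: str
    disease_filter: str = "both"  # RA | PsA | both
    responder_filter: bool = False
    cv_scheme: str = "venetian"  # venetian | kfold (recorded; GA always kfold)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.comparison not in COMPARISONS:
            raise ValueError(f"comparison must be one of {COMPARISONS}")
        if self.disease_filter not in (*DISEASES, "both"):
            raise ValueError("disease_filter must be RA, PsA or both")
        if self.comparison == "drug_contrast" and not self.responder_filter:
            raise ValueError(
                "drug_contrast runs within the responders: set responder_filter"
            )


def validate_metadata(table, comparison: str | None = None
                      ) -> tuple[pd.DataFrame, dict]:
    """Check, coerce and summarize a metadata table.

    Returns the normalized table plus per-group counts. ``delta_das28`` is
    derived as das28_12mo - das28_baseline when both columns are present.
    """
    df = (pd.read_csv(table) if isinstance(table, (str, Path))
          else table.copy())
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if comparison == "baseline_vs_12week" and "timepoint" not in df.columns:
        missing.append("timepoint")
    if missing:
        raise ValueError(f"metadata missing required column(s): {sorted(set(missing))}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    df["responder"] = df["responder"].astype(int)
    for col, allowed in (("disease", DISEASES), ("drug", DRUGS),
                         ("timepoint", TIMEPOINTS)):
        bad = set(df[col].astype(str)) - set(allowed)
        if bad:
            raise ValueError(f"unknown {col} code(s): {sorted(bad)}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        dups = df.loc[dup, ["subject_id", "timepoint"]].to_records(index=False)
        raise ValueError(f"duplicated (subject, timepoint) rows: {list(dups)[:5]}")
    if {"das28_baseline", "das28_12mo"} <= set(df.columns):
        df["delta_das28"] = df["das28_12mo"] - df["das28_baseline"]
    if comparison == "baseline_vs_12week":
        per_subject = df.groupby("subject_id")["timepoint"].agg(set)
        unpaired = [s for s, tps in per_subject.items()
                    if tps != set(TIMEPOINTS)]
        if unpaired:
            raise ValueError(
                f"baseline_vs_12week needs paired samples; unpaired subject(s): "
                f"{unpaired[:5]}"
            )
    def _vc(col):
        return {k if isinstance(k, str) else int(k): int(v)
                for k, v in df[col].value_counts().items()}

    counts = {
        "n_samples": int(len(df)),
        "by_disease": _vc("disease"),
        "by_responder": _vc("responder"),
        "by_timepoint": _vc("timepoint"),
        "by_drug": _vc("drug"),
    }
    return df, counts


def _filter_for_design(df: pd.DataFrame, design: StudyDesign
                       ) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the design's filters, recording n before/after each."""
    provenance = [{"filter": "input", "n": int(len(df))}]
    if design.disease_filter != "both":
        df = df[df["disease"] == design.disease_filter]
        provenance.append({"filter": f"disease=={design.disease_filter}",
                           "n": int(len(df))})
    if design.responder_filter:
        df = df[df["responder"] == 1]
        provenance.append({"filter": "responder==1", "n": int(len(df))})
    if design.comparison in ("response_at_baseline",):
        df = df[df["timepoint"] == "baseline"]
        provenance.append({"filter": "timepoint==baseline", "n": int(len(df))})
    elif design.comparison == "drug_contrast":
        df = df[df["timepoint"] == "week12"]
        provenance.append({"filter": "timepoint==week12", "n": int(len(df))})
    return df.reset_index(drop=True), provenance


def _class_column(comparison: str) -> tuple[str, object]:
    """Label column and default positive class for each comparison.

    For response prediction the positive class is the non-responder
    (sensitivity is quoted on detecting non-response); for the longitudinal
    contrast it is the on-therapy sample.
    """
    return {
        "response_at_baseline": ("responder", 0),
        "baseline_vs_12week": ("timepoint", "week12"),
        "drug_contrast": ("drug", "etanercept"),
    }[comparison]


def run_study(
    design: StudyDesign,
    spectra_dir: str | Path,
    metadata,
    outdir: str | Path,
    config: dict | None = None,
) -> dict:
    """Execute preprocess -> (PLS-DA + GA [+ PLS regression]) -> annotate.

    Writes ``report.json``, ``tables/*.csv`` and ``config_echo.yaml`` under
    ``outdir`` and returns the report dict. Identical config + seed give
    byte-identical report JSON.
    """
    config = config or {}
    outdir = Path(outdir)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)

    meta, counts = validate_metadata(metadata, design.comparison)
    meta, provenance = _filter_for_design(meta, design)
    label_col, default_pos = _class_column(design.comparison)
    labels = meta[label_col].to_numpy()
    if len(np.unique(labels)) != 2 or min(np.bincount(
            pd.factorize(labels)[0])) < 2:
        raise ValueError(
            f"need two classes with >=2 samples each in {label_col!r} "
            "after filtering"
        )

    spectra = {s.sample_id: s for s in read_spectra_dir(spectra_dir)}
    missing = [sid for sid in meta["sample_id"] if sid not in spectra]
    if missing:
        raise ValueError(f"spectra missing for sample(s): {missing[:5]}")
    ordered = [spectra[sid] for sid in meta["sample_id"]]

    pp_conf = dict(config.get("preprocess", {}))
    pp = PreprocessParams(**pp_conf)
    matrix = preprocess_spectra(ordered, pp)

    n_top = int(config.get("n_top", 20))
    tolerance = float(config.get("annotate", {}).get(
        "tolerance", annotate_mod.DEFAULT_TOLERANCE))
    library = default_library()
    report: dict = {
        "software": {"package": "nmrfinger", "version": __version__},
        "design": {**vars(design)},
        "metadata_counts": counts,
        "filter_provenance": provenance,
        "n_samples": int(matrix.n_samples),
        "n_bins": int(matrix.n_bins),
        "preprocess": {**vars(pp), "exclude": [list(r) for r in pp.exclude],
                       "stage_flags": sorted(matrix.stage_flags)},
    }

    # --- PLS-DA path ---------------------------------------------------
    pd_conf = config.get("plsda", {})
    k = int(pd_conf.get("k", 7))
    ncomp = int(pd_conf.get("n_components", 2))
    positive = pd_conf.get("positive_class", default_pos)
    coded, positive = plsda.encode_labels(labels, positive)
    cv = plsda.cross_validate_plsda(matrix, labels, k=k, n_components=ncomp,
                                    positive_class=positive)
    full_model = plsda.fit_pls(matrix, coded, ncomp)
    top_peaks = plsda.top_weighted_peaks(full_model, min(n_top, matrix.n_bins))
    top_peaks.to_csv(outdir / "tables" / "plsda_top_peaks.csv", index=False)
    ann_plsda = annotate_mod.match_bins(top_peaks, library, tolerance)
    report["plsda"] = {
        "cv": cv.to_dict(),
        "explained_variance_fraction":
            [float(v) for v in full_model.explained_variance_fraction],
        "top_peaks": top_peaks.to_dict(orient="records"),
    }

    # --- GA path --------------------------------------------------------
    ga_conf = dict(config.get("gaselect", {}))
    ga_conf.setdefault("seed", design.seed)
    ga_params = gaselect.GaParams(**ga_conf)
    run = gaselect.evolve(matrix, labels, ga_params)
    ranked = gaselect.rank_bins(run, min(n_top, len(run.bin_frequency)))
    ranked.to_csv(outdir / "tables" / "ga_ranked_bins.csv", index=False)
    ga_bins = ranked["bin_index"].head(ga_params.chromosome_length).tolist()
    ga_cv = gaselect.cross_validated_accuracy(
        matrix, labels, ga_bins, kfold=ga_params.kfold,
        n_repeats=int(config.get("ga_cv_repeats", 10)),
        seed=design.seed, positive_class=positive)
    scores, var_frac = gaselect.pca_of_selected(
        matrix, ranked["bin_index"].tolist())
    pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
                 ).assign(sample_id=meta["sample_id"]).to_csv(
        outdir / "tables" / "ga_pca_scores.csv", index=False)
    ann_ga = annotate_mod.match_bins(ranked, library, tolerance)
    report["gaselect"] = {
        "cv": ga_cv.to_dict(),
        "ranked_bins": ranked.to_dict(orient="records"),
        "pca_variance_fractions": [float(v) for v in var_frac],
        "params": run.to_dict()["params"],
    }

    # --- PLS regression path (optional continuous outcome) --------------
    method_annotations = {"plsda": ann_plsda, "galgo": ann_ga}
    reg_conf = config.get("plsreg", {})
    outcome_name = reg_conf.get("outcome")
    if outcome_name:
        if outcome_name not in meta.columns:
            raise ValueError(f"outcome column {outcome_name!r} not in metadata")
        y = meta[outcome_name].to_numpy(dtype=float)
        result = plsreg.permutation_test(
            matrix, y,
            max_bins=int(reg_conf.get("max_bins", 90)),
            n_components=int(reg_conf.get("n_components", 2)),
            cv_folds=reg_conf.get("cv_folds"),
            n_permutations=int(reg_conf.get("n_permutations", 100)),
            seed=design.seed,
            outcome_name=outcome_name,
        )
        sel = pd.DataFrame({
            "bin_index": result.selected_bins,
            "bin_center": matrix.bin_centers[result.selected_bins],
            "cv_r2": result.step_cv_r2 + [np.nan] * (
                len(result.selected_bins) - len(result.step_cv_r2)),
        })
        sel.to_csv(outdir / "tables" / "plsreg_selected_bins.csv", index=False)
        ann_reg = annotate_mod.match_bins(sel.head(n_top), library, tolerance)
        method_annotations["plsreg"] = ann_reg
        report["plsreg"] = result.to_dict()

    # --- annotation + consensus -----------------------------------------
    for method, anns in method_annotations.items():
        annotate_mod.annotations_to_frame(anns).to_csv(
            outdir / "tables" / f"annotations_{method}.csv", index=False)
    consensus = annotate_mod.consensus_metabolites(method_annotations)
    consensus.to_csv(outdir / "tables" / "consensus.csv", index=False)
    report["consensus"] = consensus.to_dict(orient="records")

    if config.get("plots"):
        (outdir / "figures").mkdir(exist_ok=True)
        plots.score_plot(full_model, labels, outdir / "figures" / "plsda_scores.png")
        plots.weighting_plot(full_model, outdir / "figures" / "plsda_weightings.png")
        plots.pca_plot(scores, var_frac, labels, outdir / "figures" / "ga_pca.png")

    (outdir / "config_echo.yaml").write_text(
        yaml.safe_dump({"design": vars(design), "config": config},
                       sort_keys=True))
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False,
                   default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
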