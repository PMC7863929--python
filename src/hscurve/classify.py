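"""Two-step threshold-cascade classification and confusion-matrix evaluation.

The cascade mirrors how a dermatologist triages pigmented skin lesions
(PSLs), most urgent first:

  Step 1  melanoma      iff  max totm > c            (c = 2.86)
  Step 2  malignant     iff  max mean > d  or  max prod > e   (d = 0.05, e = 0.395)
          else benign   iff  min mean < g  or  min mabdf < f  (g = 0.05, f = 0.109)
          else the mean-above/below-g boundary decides.

All inequalities are strict; threshold equality falls through.  When both
step-2 rules could fire (the extrema come from different windows) malignant
wins — the cautious call for a screening tool.  Evaluation treats
{melanoma, malignant} as the positive class and additionally scores the
melanoma-vs-rest task.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import HscurveError, IdentifiabilityError
from .features import CubeFeatureSummary, CurveFeatures, compute_features, summarize_cube
from .fitting import FitOptions, QuarticFit, fit_quartic
from .io import HSICube, RawCube, ReferenceSet, calibrate, normalize, read_cube, read_references
from .roi import prune, sweep

logger = logging.getLogger("hscurve")

__all__ = [
    "ClassLabel",
    "ClassifierConfig",
    "EvaluationReport",
    "classify",
    "evaluate",
    "analyze_cube",
    "run_pipeline",
]


class ClassLabel(str, Enum):
    MELANOMA = "melanoma"
    MALIGNANT = "malignant"
    BENIGN = "benign"

    def positive(self) -> bool:
        """True for the cancerous classes (melanoma and other malignant)."""
        return self is not ClassLabel.BENIGN


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision constants of the cascade (trained values; see module docstring).

    a, b weight the derivative terms inside totm; c..g are the thresholds.
    d and g both default to 0.05 but are independently settable (d bounds
    the malignant mean from below, g the benign mean from above).
    """

    a: float = 1.0
    b: float = 0.1
    c: float = 2.86
    d: float = 0.05
    e: float = 0.395
    f: float = 0.109
    g: float = 0.05

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not math.isfinite(v):
                raise ValueError(f"threshold {name} must be finite, got {v}")


def classify(summary: CubeFeatureSummary, cfg: ClassifierConfig | None = None) -> ClassLabel:
    """Apply the threshold cascade to one cube's feature summary."""
    cfg = cfg or ClassifierConfig()
    fields = (summary.max_totm, summary.max_mean, summary.max_prod,
              summary.min_mean, summary.min_mabdf)
    if not all(math.isfinite(v) for v in fields):
        raise HscurveError(f"non-finite feature summary: {fields}")
    if summary.max_totm > cfg.c:
        return ClassLabel.MELANOMA
    if summary.max_mean > cfg.d or summary.max_prod > cfg.e:
        return ClassLabel.MALIGNANT
    if summary.min_mean < cfg.g or summary.min_mabdf < cfg.f:
        return ClassLabel.BENIGN
    return ClassLabel.MALIGNANT if summary.max_mean > cfg.g else ClassLabel.BENIGN


@dataclass
class EvaluationReport:
    """Binary confusion counts and derived rates; NaN marks an undefined rate."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    melanoma_sensitivity: float
    melanoma_specificity: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def evaluate(pred: Sequence[ClassLabel], truth: Sequence[ClassLabel]) -> EvaluationReport:
    """Confusion counts and rates for predictions against ground truth.

    Positive = {melanoma, malignant}.  A malignant lesion predicted
    melanoma (or vice versa) still counts as a true positive for the
    binary task; the melanoma-vs-rest rates score the finer call.
    """
    if len(pred) != len(truth):
        raise ValueError(f"{len(pred)} predictions vs {len(truth)} truths")
    if len(pred) == 0:
        raise ValueError("nothing to evaluate")
    tp = sum(1 for p, t in zip(pred, truth) if t.positive() and p.positive())
    fn = sum(1 for p, t in zip(pred, truth) if t.positive() and not p.positive())
    fp = sum(1 for p, t in zip(pred, truth) if not t.positive() and p.positive())
    tn = sum(1 for p, t in zip(pred, truth) if not t.positive() and not p.positive())
    mel_tp = sum(1 for p, t in zip(pred, truth)
                 if t is ClassLabel.MELANOMA and p is ClassLabel.MELANOMA)
    mel_t = sum(1 for t in truth if t is ClassLabel.MELANOMA)
    mel_tn = sum(1 for p, t in zip(pred, truth)
                 if t is not ClassLabel.MELANOMA and p is not ClassLabel.MELANOMA)
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_rate(tp + tn, len(pred)),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        melanoma_sensitivity=_rate(mel_tp, mel_t),
        melanoma_specificity=_rate(mel_tn, len(truth) - mel_t),
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def analyze_cube(
    cube: HSICube,
    cfg: ClassifierConfig | None = None,
    fit_opts: FitOptions | None = None,
    start: tuple[int, int] = (16, 16),
    end: tuple[int, int] = (35, 35),
    prune_threshold: float = 3.0,
    prune_bins: int = 50,
    totm_variant: str = "text",
) -> tuple[ClassLabel, CubeFeatureSummary, list[CurveFeatures], list[QuarticFit]]:
    """Sweep, prune, fit and classify one normalized cube.

    Windows whose curve cannot identify a quartic (e.g. a constant region)
    are dropped with a log message; at least one candidate must survive.
    """
    cfg = cfg or ClassifierConfig()
    fit_opts = fit_opts or FitOptions()
    curves = sweep(cube, start=start, end=end)
    feats: list[CurveFeatures] = []
    fits: list[QuarticFit] = []
    for curve in curves:
        pruned = prune(curve, threshold=prune_threshold, bins=prune_bins)
        try:
            fit = fit_quartic(pruned, fit_opts)
        except IdentifiabilityError:
            logger.debug("window %s: unidentifiable curve, skipped", curve.window.center)
            continue
        fits.append(fit)
        feats.append(compute_features(fit, pruned, a=cfg.a, b=cfg.b,
                                      totm_variant=totm_variant))  # type: ignore[arg-type]
    if not feats:
        raise HscurveError("no candidate window produced a fittable curve")
    summary = summarize_cube(feats)
    return classify(summary, cfg), summary, feats, fits


def _features_frame(feats: list[CurveFeatures]) -> pd.DataFrame:
    rows = []
    for f in feats:
        r, c = f.window.center if f.window is not None else (-1, -1)
        rows.append({
            "window_row": r, "window_col": c, "totm": f.totm, "mean": f.mean,
            "prod": f.prod, "mabdf": f.mabdf, "df_mean": f.df_mean,
            "ddf_mean": f.ddf_mean, "df_at_max": f.df_at_max,
            "abs_df_mean": f.abs_df_mean, "inflections": f.inflections,
        })
    return pd.DataFrame(rows)


def run_pipeline(
    raw_path: str | Path,
    refs_path: str | Path,
    cfg: ClassifierConfig | None = None,
    out_dir: str | Path | None = None,
    fit_opts: FitOptions | None = None,
    **analyze_kw,
) -> ClassLabel:
    """Calibrate -> normalize -> sweep -> prune -> fit -> features -> classify.

    ``raw_path`` is a cube file (npz or ENVI header), ``refs_path`` an npz
    with 'white' and 'dark'.  When ``out_dir`` is given, writes curves.csv,
    fits.json, features.csv and decision.json; decision.json is a pure
    function of the inputs and configuration (no timestamps), so repeated
    runs are byte-identical.
    """
    cfg = cfg or ClassifierConfig()
    fit_opts = fit_opts or FitOptions()
    try:
        cube_in = read_cube(raw_path)
        if isinstance(cube_in, RawCube):
            refs: ReferenceSet = read_references(refs_path)
            cube = normalize(calibrate(cube_in, refs))
        else:
            cube = normalize(cube_in)
    except HscurveError as err:
        raise HscurveError(f"[load/calibrate] {err}") from err

    try:
        label, summary, feats, fits = analyze_cube(cube, cfg, fit_opts, **analyze_kw)
    except HscurveError as err:
        raise HscurveError(f"[analyze] {err}") from err

    logger.info("cube %s -> %s (max_totm=%.4f max_mean=%.4f min_mabdf=%.4f)",
                cube.id, label.value, summary.max_totm, summary.max_mean, summary.min_mabdf)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        curves = sweep(cube, start=analyze_kw.get("start", (16, 16)),
                       end=analyze_kw.get("end", (35, 35)))
        rows = []
        for curve in curves:
            r, c = curve.window.center
            for k in range(len(curve)):
                rows.append((cube.id, r, c, k, cube.wavelengths[k], curve.x[k], curve.y[k]))
        pd.DataFrame(rows, columns=["cube_id", "window_row", "window_col", "band_index",
                                    "wavelength_nm", "mean", "std"]).to_csv(
            out / "curves.csv", index=False)
        with open(out / "fits.json", "w") as fh:
            json.dump([{ "window": list(f.window.center) if f.window else None,
                         "coeffs": list(fit.coeffs), "x_range": list(fit.x_range),
                         "converged": fit.converged, "n_iter": fit.n_iter,
                         "objective": fit.objective, "mse": fit.mse,
                         "n_points": fit.n_points }
                       for f, fit in zip(feats, fits)], fh, indent=1)
        _features_frame(feats).to_csv(out / "features.csv", index=False)
        decision = {
            "cube_id": cube.id,
            "label": label.value,
            "summary": {
                "max_totm": summary.max_totm, "max_mean": summary.max_mean,
                "max_prod": summary.max_prod, "min_mean": summary.min_mean,
                "min_mabdf": summary.min_mabdf, "n_curves": summary.n_curves,
                "arg_windows": {k: list(v) if v else None
                                for k, v in summary.arg_windows.items()},
            },
            "config": asdict(cfg),
            "fit_options": asdict(fit_opts),
        }
        with open(out / "decision.json", "w") as fh:
            json.dump(decision, fh, indent=1, sort_keys=True)
    return label
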