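"""End-to-end analysis pipeline: read/generate -> exclude -> winsorize ->
correlate -> select covariates -> fit LMS charts -> tabulate.

All stage outputs are plain CSV/JSON (plus SVG charts) in the configured
output directory; a run manifest records the configuration, input hash and
per-stage summaries.  Every source of randomness flows from the single
configured seed, and a fixed ``timestamp`` makes reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlation_matrix
from .cohort import (
    COHORT_COLUMNS,
    GeneratorParams,
    generate_cohort,
    make_fixture_129,
)
from .lms import DEFAULT_CENTILES, LMS, df_grid_search
from .qc import apply_exclusions, semi_winsorize
from .selection import ForwardSelection

log = logging.getLogger("pedqus")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_cohort_csv",
    "write_cohort_csv",
    "run_pipeline",
]

_NUMERIC_COLS = [
    "age", "height_sds", "weight_sds", "bmi_sds", "wall_mm", "liver_pct",
    "spleen_pct", "portal_v", "hepatic_v", "fasting_h", "swd_depth_cm",
    "ati", "swe_ms", "swe_kpa", "swd",
]

#: Sonography outcomes winsorized and charted by default, with unit labels.
DEFAULT_OUTCOMES = {
    "ati": "dB/cm/MHz",
    "swe_ms": "m/s",
    "swe_kpa": "kPa",
    "swd": "(m/s)/kHz",
}

#: Candidate covariates entering subset selection (binary ones 0/1-coded).
BASE_CANDIDATES = [
    "age", "sex01", "bmi_sds", "height_sds", "wall_mm", "liver_pct",
    "spleen_pct", "fasting_h", "coop01",
]

#: Fallback chart covariate when selection retains nothing continuous.
DEFAULT_CHART_COVARIATE = {
    "ati": "age",
    "swe_ms": "wall_mm",
    "swe_kpa": "wall_mm",
    "swd": "bmi_sds",
}

#: Variables entering the bivariate correlation battery.
CORRELATION_VARIABLES = [
    "ati", "swe_ms", "swe_kpa", "swd", "age", "height_sds", "bmi_sds",
    "liver_pct", "spleen_pct", "wall_mm", "sex", "fasting_h",
    "swd_depth_cm", "cooperation",
]


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical dialect (empty field = NA)."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    out = df[cols].copy()
    if "enzymes_elevated" in out:
        out["enzymes_elevated"] = out["enzymes_elevated"].map(
            {True: "true", False: "false"}
        )
    out.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV into a typed table.

    Columns are matched by name (any order); unknown columns are preserved
    untouched.  A missing required column raises a schema error listing the
    differences; a malformed numeric cell raises an error naming its row
    (1-based, counting the header) and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        extra = [c for c in raw.columns if c not in COHORT_COLUMNS]
        raise ValueError(
            f"cohort header mismatch in {path}: missing {missing}"
            + (f"; unrecognized {extra}" if extra else "")
        )
    df = raw.copy()
    for col in _NUMERIC_COLS:
        vals = raw[col].str.strip()
        empty = vals == ""
        num = pd.to_numeric(vals.where(~empty), errors="coerce")
        bad = (~empty) & num.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ValueError(
                f"malformed numeric value {vals[bad].iloc[0]!r} in column "
                f"{col!r} at line {row} of {path}"
            )
        df[col] = num
    flags = raw["enzymes_elevated"].str.strip().str.lower()
    valid = flags.isin(["true", "false", "1", "0"])
    if not valid.all():
        row = int(np.argmax(~valid.to_numpy())) + 2
        raise ValueError(
            f"malformed boolean in column 'enzymes_elevated' at line {row}"
        )
    df["enzymes_elevated"] = flags.isin(["true", "1"])
    ordered = [c for c in COHORT_COLUMNS if c in df.columns]
    ordered += [c for c in df.columns if c not in ordered]
    return df[ordered]


# ---------------------------------------------------------------------------
# Configuration and manifest
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "pedqus_out"
    input: str | None = None        # cohort CSV; None -> generate
    fixture: bool = False           # use the packaged 129-record fixture
    n: int = 2000                   # generator size when generating
    outcomes: tuple[str, ...] = tuple(DEFAULT_OUTCOMES)
    winsorize_k: float = 2.5
    alpha: float = 0.05
    bootstrap_B: int = 500
    cv_folds: int = 10
    df_max: int = 5
    centiles: tuple[float, ...] = DEFAULT_CENTILES
    stratify: dict = field(default_factory=dict)  # outcome -> column or ""
    timestamp: str = "now"          # "now" or a fixed ISO-8601 string

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kw = dict(raw)
        for key in ("outcomes", "centiles"):
            if key in kw and isinstance(kw[key], str):
                kw[key] = tuple(
                    type_ (v) for v, type_ in
                    ((s.strip(), float if key == "centiles" else str)
                     for s in kw[key].split(","))
                )
            elif key in kw:
                kw[key] = tuple(kw[key])
        cfg = cls(**kw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for o in self.outcomes:
            if o not in DEFAULT_OUTCOMES:
                raise ValueError(
                    f"unknown outcome {o!r}; known: {sorted(DEFAULT_OUTCOMES)}"
                )
        if self.winsorize_k <= 0:
            raise ValueError("winsorize_k must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.df_max <= 5:
            raise ValueError("df_max must lie in 0..5")
        for c in self.centiles:
            if not 0 < c < 1:
                raise ValueError(f"centile levels must lie in (0,1), got {c}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcomes"] = list(self.outcomes)
        d["centiles"] = list(self.centiles)
        # where the outputs land is not part of the analysis definition
        d.pop("outdir")
        return d


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    input_hash: str
    version: str
    started_at: str
    finished_at: str = ""
    stages: dict = field(default_factory=dict)
    completed: bool = False
    error: str = ""

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _json_dump(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _with_codes(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["sex01"] = (out["sex"] == "female").astype(float)
    out["coop01"] = (out["cooperation"] == "restless").astype(float)
    return out


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _stage_cohort(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    if cfg.input:
        df = read_cohort_csv(cfg.input)
        src = f"file:{cfg.input}"
    elif cfg.fixture:
        df = make_fixture_129()
        src = "fixture_129"
    else:
        df = generate_cohort(GeneratorParams(n=cfg.n, seed=cfg.seed))
        src = f"generated(n={cfg.n})"
    write_cohort_csv(df, outdir / "cohort.csv")
    log.info("cohort stage: %d records from %s", len(df), src)
    return df


def _stage_qc(cfg: PipelineConfig, df: pd.DataFrame, outdir: Path):
    retained, audit = apply_exclusions(df)
    _json_dump(audit.to_dict(), outdir / "exclusion_audit.json")
    cleaned = retained.copy()
    win_audit = {}
    for outcome in cfg.outcomes:
        res = semi_winsorize(retained[outcome].to_numpy(float), cfg.winsorize_k)
        cleaned[outcome] = res.values
        n_obs = int(np.isfinite(res.values).sum())
        win_audit[outcome] = {
            "lower_bound": res.lower_bound,
            "upper_bound": res.upper_bound,
            "median": res.median,
            "mad_scaled": res.mad_scaled,
            "k": res.k,
            "n_obs": n_obs,
            "n_replaced": res.n_replaced,
            "replaced_fraction": res.replaced_fraction,
            "replaced_ids": retained["id"].iloc[res.replaced_indices].tolist(),
        }
    _json_dump(win_audit, outdir / "winsorize_audit.json")
    write_cohort_csv(cleaned, outdir / "cohort_clean.csv")
    log.info("qc stage: retained %d/%d", audit.n_retained, audit.n_input)
    return cleaned, audit, win_audit


def _stage_correlate(cfg: PipelineConfig, cleaned: pd.DataFrame, outdir: Path):
    variables = [v for v in CORRELATION_VARIABLES if v in cleaned.columns]
    matrix = correlation_matrix(cleaned, variables)
    matrix.r_frame().to_csv(outdir / "correlations.csv")
    _json_dump(matrix.to_records(), outdir / "correlations.json")
    log.info("correlation stage: %d variables", len(variables))
    return matrix


def _stage_select(cfg: PipelineConfig, cleaned: pd.DataFrame, outdir: Path,
                  seeds) -> dict:
    coded = _with_codes(cleaned)
    selections: dict[str, dict] = {}
    # kPa and m/s SWE share one selection (identical dependence pattern)
    to_run = [o for o in cfg.outcomes if o != "swe_kpa"]
    for i, outcome in enumerate(to_run):
        candidates = list(BASE_CANDIDATES)
        if outcome == "swd":
            candidates.append("swd_depth_cm")
        sel = ForwardSelection.from_dataframe(
            coded, outcome, candidates, alpha=cfg.alpha, B=cfg.bootstrap_B,
            k_folds=cfg.cv_folds, seed=int(seeds[i]),
        ).fit()
        selections[outcome] = sel.to_dict()
        _json_dump(sel.to_dict(), outdir / f"selection_{outcome}.json")
        (outdir / f"selection_{outcome}.txt").write_text(
            sel.summary() + "\n", encoding="utf-8"
        )
        log.info("selection stage: %s -> %s", outcome, sel.chosen_subset)
    if "swe_kpa" in cfg.outcomes and "swe_ms" in selections:
        selections["swe_kpa"] = dict(selections["swe_ms"], outcome="swe_kpa")
        _json_dump(selections["swe_kpa"], outdir / "selection_swe_kpa.json")
    return selections


def _chart_plan(cfg: PipelineConfig, outcome: str, selection: dict):
    """Chart covariate and stratification implied by the selected subset."""
    subset = selection["chosen_subset"]
    continuous = [c for c in subset if c not in ("sex01", "coop01")]
    covariate = continuous[0] if continuous else DEFAULT_CHART_COVARIATE[outcome]
    stratify = cfg.stratify.get(outcome)
    if stratify is None:
        stratify = "sex" if "sex01" in subset else ""
    return covariate, stratify


def _fit_one_chart(cfg, data, outcome, covariate, label, outdir):
    grid = [
        (a, b, c)
        for a in range(cfg.df_max + 1)
        for b in range(cfg.df_max + 1)
        for c in range(cfg.df_max + 1)
    ]
    x = data[covariate].to_numpy(float)
    y = data[outcome].to_numpy(float)
    keep = np.isfinite(x) & np.isfinite(y)
    model = LMS(x[keep], y[keep], (0, 0, 0), xname=covariate, yname=outcome,
                stratum=label or None)
    best, table = df_grid_search(
        x[keep], y[keep], grid, xname=covariate, yname=outcome,
        stratum=label or None,
    )
    suffix = f"{outcome}_{label}" if label else outcome
    table.to_csv(outdir / f"bic_grid_{suffix}.csv", index=False)
    best.to_json(outdir / f"model_{suffix}.json")
    ptable = best.reference_table(cfg.centiles)
    ptable.to_csv(outdir / f"percentiles_{suffix}.csv")
    _save_chart(best, cfg.centiles, outdir / f"chart_{suffix}.svg")
    return best


def _save_chart(results, centiles, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with matplotlib.rc_context({"svg.hashsalt": "pedqus"}):
        ax = results.plot_centiles(centiles)
        ax.figure.savefig(path, format="svg", metadata={"Date": None})
        plt.close(ax.figure)


def _stage_fit(cfg: PipelineConfig, cleaned: pd.DataFrame, outdir: Path,
               selections: dict) -> dict:
    fitted: dict[str, dict] = {}
    for outcome in cfg.outcomes:
        covariate, stratify = _chart_plan(cfg, outcome, selections[outcome])
        info = {"covariate": covariate, "stratify": stratify, "strata": {}}
        if stratify:
            for level, group in cleaned.groupby(stratify, sort=True):
                best = _fit_one_chart(cfg, group, outcome, covariate,
                                      str(level), outdir)
                info["strata"][str(level)] = {
                    "dfs": list(best.model.dfs), "bic": best.bic, "n": best.n,
                }
        else:
            best = _fit_one_chart(cfg, cleaned, outcome, covariate, "", outdir)
            info["strata"][""] = {
                "dfs": list(best.model.dfs), "bic": best.bic, "n": best.n,
            }
        fitted[outcome] = info
        log.info("fit stage: %s ~ %s%s", outcome, covariate,
                 f" by {stratify}" if stratify else "")
    return fitted


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages; outputs land in ``config.outdir``.

    Stages run in order (exclusions -> winsorize -> correlate -> select ->
    fit/tabulate); outputs of completed stages are written even when a later
    stage fails, and the manifest records how far the run got.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = (
        datetime.now(timezone.utc).isoformat(timespec="seconds")
        if config.timestamp == "now"
        else config.timestamp
    )
    manifest = RunManifest(
        config=config.to_dict(), input_hash="", version=__version__,
        started_at=stamp,
    )
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    try:
        df = _stage_cohort(config, outdir)
        manifest.input_hash = _sha256(outdir / "cohort.csv")
        manifest.stages["cohort"] = {"n": len(df)}

        cleaned, audit, win_audit = _stage_qc(config, df, outdir)
        manifest.stages["qc"] = {
            "n_retained": audit.n_retained,
            "n_enzyme_excluded": audit.n_enzyme_excluded,
            "n_bmi_excluded": audit.n_bmi_excluded,
            "winsorized": {o: a["n_replaced"] for o, a in win_audit.items()},
        }

        matrix = _stage_correlate(config, cleaned, outdir)
        manifest.stages["correlate"] = {"n_pairs": len(matrix.results)}

        selections = _stage_select(config, cleaned, outdir, seeds)
        manifest.stages["select"] = {
            o: s["chosen_subset"] for o, s in selections.items()
        }

        fitted = _stage_fit(config, cleaned, outdir, selections)
        manifest.stages["fit"] = fitted
        manifest.completed = True
    except Exception as exc:  # noqa: BLE001 - recorded, then re-raised by CLI
        manifest.error = f"{type(exc).__name__}: {exc}"
        log.error("pipeline failed: %s", manifest.error)
    finally:
        manifest.finished_at = stamp if config.timestamp != "now" else (
            datetime.now(timezone.utc).isoformat(timespec="seconds")
        )
        manifest.to_json(outdir / "manifest.json")
    return manifest
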