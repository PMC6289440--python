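"""End-to-end orchestration: simulate -> treelet -> CV -> score -> Cox -> report.

Every stage writes inspectable CSV/JSON intermediates with a provenance
block (config hash, seed, package version), and an identical config + seed
reproduces byte-identical outputs. Stages can be re-run from saved
intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .channels import CHANNEL_IDS, COMMON_NAMES
from .cv import CVResult, cross_validate
from .survival import CaseCohortCox, CoxFit
from .synthetic import (
    BlockSpec,
    ChannelMoments,
    HazardSpec,
    generate_cohort,
    generate_panel,
    sample_case_cohort,
    true_block_scores,
)
from .treelet import (
    FactorSet,
    StandardizationParams,
    TreeletTransform,
    score_subjects,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "render_loadings_table",
    "render_hr_table",
    "format_p",
    "dendrogram_json",
    "dendrogram_newick",
]

log = logging.getLogger("treeletcox")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str = "treeletcox_run"
    seed: int = 0
    # simulation (used when panel_csv/cohort_csv are not given)
    n_cohort: int = 57053
    subcohort_size: int = 3500
    within_rho: float = 0.6
    between_rho: float = 0.05
    log_hr_per_factor: tuple[float, ...] | None = None
    # existing inputs
    panel_csv: str | None = None
    cohort_csv: str | None = None
    # cross-validation
    cv_folds: int = 5
    cv_levels: tuple[int, ...] | None = None
    cv_m_values: tuple[int, ...] | None = None
    cv_tau: float = 0.01
    # overrides for the CV choice
    cut_level: int | None = None
    n_factors: int | None = None
    # survival analysis
    weight_scheme: str = "barlow"
    barlow_eps: float = 1e-5
    models: tuple[str, ...] = ("model1", "model1a", "model2")
    sexes: tuple[str, ...] = ("male", "female")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("log_hr_per_factor", "cv_levels", "cv_m_values", "models", "sexes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Artifacts of one pipeline run (in memory + paths on disk)."""

    config: RunConfig
    factors: FactorSet
    cv: CVResult | None
    loadings_table: pd.DataFrame
    hr_tables: dict[str, pd.DataFrame]          # sex -> rendered table
    fits: dict[tuple[str, str, str], CoxFit]    # (sex, factor, model) -> fit
    scores: pd.DataFrame
    outdir: Path

    @property
    def cumulative_pct(self) -> float:
        return self.factors.cumulative_pct


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _write_with_provenance(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """CSV with provenance carried in leading comment lines."""
    prov = _provenance(config)
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=True)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV, skipping provenance comment lines."""
    return pd.read_csv(path, comment="#", **kwargs)


def format_hr(hr: float, lo: float, hi: float) -> str:
    return f"{hr:.2f} ({lo:.2f}–{hi:.2f})"


def format_p(p: float) -> str:
    """Trend p-value display: floor tiny values at '0.0000'.

    p < 0.00005 prints as 0.0000; below 0.01 with 2 significant figures;
    otherwise 2 decimals.
    """
    if p < 0.00005:
        return "0.0000"
    if p < 0.01:
        return f"{p:.2g}"
    return f"{p:.2f}"


def render_loadings_table(
    factors: FactorSet,
    common_names: dict[str, str] | None = None,
    zero_tol: float = 0.005,
) -> pd.DataFrame:
    """Channels x factors loadings table with blanks for structural zeros.

    Loadings print to 1 decimal; entries below ``zero_tol`` in magnitude are
    blank. Final rows carry the per-factor explained variance (%) and the
    cumulative percentage (full precision is kept in the FactorSet itself).
    """
    if factors.m < 1:
        raise ValueError("need at least one factor")
    names = common_names or COMMON_NAMES
    cols = [f"TT{k + 1}" for k in range(factors.m)]
    rows = {}
    for i, ch in enumerate(factors.channel_ids):
        cells = []
        for k in range(factors.m):
            v = factors.loadings[i, k]
            cells.append("" if abs(v) < zero_tol else f"{v:.1f}")
        rows[ch] = cells
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.insert(0, "common_name", [names.get(c, "") for c in table.index])
    ev = [f"{v:.1f}" for v in factors.explained_variance_pct]
    table.loc["Explained variance (%)"] = [""] + ev
    table.loc["Cumulative (%)"] = [""] + [f"{factors.cumulative_pct:.0f}"] + [""] * (
        factors.m - 1
    )
    table.index.name = "channel"
    return table


def render_hr_table(fits: dict[tuple[str, str], CoxFit] | list[CoxFit]) -> pd.DataFrame:
    """Quintile HR table for one sex: rows factor x (quintiles, P(trend)).

    Columns are the fitted model levels; the reference quintile prints
    exactly ``1.00 (ref.)``. Missing model levels are omitted with a warning.
    """
    import warnings as _warnings

    if isinstance(fits, list):
        fits = {(f.factor, f.model): f for f in fits}
    factors = sorted({k[0] for k in fits}, key=lambda s: (len(s), s))
    models = [m for m in ("model1", "model1a", "model2") if any(k[1] == m for k in fits)]
    for m in ("model1", "model1a", "model2"):
        if m not in models:
            _warnings.warn(f"model level {m} missing; column omitted", stacklevel=2)
    rows = []
    index = []
    for fac in factors:
        for q in range(1, 6):
            row = {}
            for m in models:
                fit = fits.get((fac, m))
                if fit is None:
                    row[m] = ""
                elif q == 1:
                    row[m] = "1.00 (ref.)"
                else:
                    row[m] = format_hr(fit.hr[q], *fit.ci[q])
            rows.append(row)
            index.append((fac, str(q)))
        row = {}
        for m in models:
            fit = fits.get((fac, m))
            row[m] = format_p(fit.trend_p) if fit and fit.trend_p is not None else ""
        rows.append(row)
        index.append((fac, "P(trend)"))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["factor", "quintile"])
    )


def dendrogram_json(model) -> str:
    """Merge schedule as JSON (levels, rotated pair, angle, sum/detail)."""
    payload = {
        "channel_ids": list(model.channel_ids),
        "merges": [
            {
                "level": m.level,
                "pair": [int(m.i), int(m.j)],
                "theta": float(m.theta),
                "sum_index": int(m.sum_index),
                "diff_index": int(m.diff_index),
            }
            for m in model.merges
        ],
    }
    return json.dumps(payload, indent=2)


def dendrogram_newick(model) -> str:
    """Dendrogram as a Newick string; branch lengths are merge-level gaps.

    Channel identifiers contain ':' so leaf labels are single-quoted.
    """
    trees = {k: f"'{ch}'" for k, ch in enumerate(model.channel_ids)}
    heights = {k: 0 for k in range(model.p)}
    for m in model.merges:
        left, right = trees[m.i], trees[m.j]
        bl_left = m.level - heights[m.i]
        bl_right = m.level - heights[m.j]
        node = f"({left}:{bl_left},{right}:{bl_right})"
        trees[m.sum_index] = node
        heights[m.sum_index] = m.level
        del trees[m.diff_index]
    (root,) = trees.values()
    return root + ";"


def _simulate(config: RunConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate panel + cohort + case-cohort sample under the config."""
    rng = np.random.default_rng(config.seed)
    r_panel, r_cohort, r_cc = rng.spawn(3)
    blocks = BlockSpec(within_rho=config.within_rho, between_rho=config.between_rho)
    moments = ChannelMoments()
    panel = generate_panel(config.n_cohort, moments, blocks, r_panel)
    scores_true = true_block_scores(panel, moments, blocks)
    hazard = (
        HazardSpec(log_hr_per_factor=tuple(config.log_hr_per_factor))
        if config.log_hr_per_factor is not None
        else HazardSpec()
    )
    cohort = generate_cohort(config.n_cohort, hazard, scores_true, r_cohort)
    log.info("simulated cohort: n=%d, events=%d", len(cohort), int(cohort["event"].sum()))
    cc = sample_case_cohort(cohort, config.subcohort_size, r_cc)
    log.info(
        "case-cohort sample: n=%d (subcohort %d, cases %d)",
        len(cc), int(cc["subcohort"].sum()), int(cc["event"].sum()),
    )
    panel_cc = panel.loc[cc["subject_id"].to_numpy()]
    panel_cc.insert(0, "subject_id", cc["subject_id"].to_numpy())
    _write_with_provenance(panel_cc.set_index("subject_id"), outdir / "panel.csv", config)
    _write_with_provenance(cc.set_index("subject_id"), outdir / "cohort.csv", config)
    return panel_cc.set_index("subject_id"), cc.set_index("subject_id")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write every artifact under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")

    # --- stage 1: data -----------------------------------------------------
    if config.panel_csv and config.cohort_csv:
        panel = read_csv(config.panel_csv, index_col="subject_id")
        records = read_csv(config.cohort_csv, index_col="subject_id")
        log.info("loaded panel %s and cohort %s", config.panel_csv, config.cohort_csv)
    else:
        panel, records = _simulate(config, outdir)

    # --- stage 2: drop incomplete panels, fit treelet on the subcohort -----
    channel_cols = [c for c in panel.columns if c in CHANNEL_IDS] or list(panel.columns)
    complete = panel[channel_cols].notna().all(axis=1)
    if (~complete).any():
        log.info("excluded %d subjects with missing channels", int((~complete).sum()))
    panel = panel.loc[complete, channel_cols]
    records = records.loc[records.index.intersection(panel.index)]
    sub_ids = records.index[records["subcohort"] == 1]
    sub_panel = panel.loc[sub_ids]
    log.info("reference (subcohort) panel: n=%d, p=%d", *sub_panel.shape)

    # --- stage 3: cross-validated cut selection ----------------------------
    cv = None
    cut_level, n_factors = config.cut_level, config.n_factors
    if cut_level is None or n_factors is None:
        cv = cross_validate(
            sub_panel,
            K=config.cv_folds,
            cut_levels=list(config.cv_levels) if config.cv_levels else None,
            m_values=list(config.cv_m_values) if config.cv_m_values else None,
            seed=np.random.default_rng(config.seed + 1),
            tau=config.cv_tau,
        )
        cut_level = cut_level if cut_level is not None else cv.chosen_cut_level
        n_factors = n_factors if n_factors is not None else cv.chosen_m
        _write_with_provenance(cv.to_frame(), outdir / "cv_scores.csv", config)
        log.info("cross-validation chose cut level %d, m=%d", cut_level, n_factors)

    tt = TreeletTransform(cut_level=cut_level, n_factors=n_factors).fit(sub_panel)
    (outdir / "dendrogram.json").write_text(dendrogram_json(tt.model_))
    (outdir / "dendrogram.nwk").write_text(dendrogram_newick(tt.model_))
    loadings_table = render_loadings_table(tt.factors_)
    _write_with_provenance(loadings_table, outdir / "loadings.csv", config)
    log.info(
        "retained %d factors, cumulative explained variance %.1f%%",
        tt.factors_.m, tt.factors_.cumulative_pct,
    )

    # --- stage 4: scores for everyone analyzed -----------------------------
    scores = score_subjects(panel, tt.params_, tt.factors_)
    _write_with_provenance(scores, outdir / "scores.csv", config)

    # --- stage 5: sex-stratified weighted Cox ladder -----------------------
    fits: dict[tuple[str, str, str], CoxFit] = {}
    hr_tables: dict[str, pd.DataFrame] = {}
    for sex in config.sexes:
        sex_records = records.loc[records["sex"] == sex]
        sex_fits = []
        for k in range(tt.factors_.m):
            factor = f"TT{k + 1}"
            est = CaseCohortCox(
                models=tuple(config.models),
                weight_scheme=config.weight_scheme,
                eps=config.barlow_eps,
            ).fit(sex_records, scores[factor], factor=factor)
            for model, fit in est.fits_.items():
                fits[(sex, factor, model)] = fit
                sex_fits.append(fit)
        table = render_hr_table(sex_fits)
        hr_tables[sex] = table
        _write_with_provenance(table, outdir / f"hr_{sex}.csv", config)
        log.info("fitted Cox ladder for %s: %d fits", sex, len(sex_fits))

    (outdir / "provenance.json").write_text(json.dumps(_provenance(config), indent=2))
    return RunReport(
        config=config,
        factors=tt.factors_,
        cv=cv,
        loadings_table=loadings_table,
        hr_tables=hr_tables,
        fits=fits,
        scores=scores,
        outdir=outdir,
    )
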