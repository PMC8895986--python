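"""Factorial experiment driver, gain/variance summaries, ANOVA and reports.

The full design crosses six two-level factors — nGP (24/96), heritability
(0.2/0.5), Ne (60/600), NumCross (400/1,000), SelectSP (random/pheno) and
CycleTime (2/1 years) — for 64 settings, each replicated.  Per replicate the
scalar responses are the 10-year genetic gain (year-10 minus year-2 GP-cohort
genetic mean), the final genetic variance and the final GS accuracy.

Founder populations are expensive, so they are cached per (Ne, replicate)
and shared by the 32 settings at that Ne: the sweep remains a pure function
of (design, base seed) and the factorial contrasts are paired on common
founders.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .founders import FounderConfig, simulate_founders
from .genetics import GenomeParams, TraitModel, error_variance_for_h2
from .scheme import MetricsRecord, SchemeConfig, run_scheme

__all__ = [
    "FactorialDesign",
    "Setting",
    "RunResult",
    "FactorialResults",
    "run_factorial",
    "gain_summary",
    "all_interventions_fold",
    "anova_table",
    "report",
]

FACTOR_LEVELS = {
    "nGP": (24, 96),
    "h2": (0.2, 0.5),
    "Ne": (60, 600),
    "NumCross": (400, 1000),
    "SelectSP": ("random", "pheno"),
    "CycleTime": (2, 1),
}
#: reference -> intervention direction for each scheme factor
INTERVENTIONS = {
    "SelectSP": ("random", "pheno"),
    "NumCross": (400, 1000),
    "CycleTime": (2, 1),
    "nGP": (24, 96),
}
SCHEME_FACTORS = tuple(INTERVENTIONS)


@dataclass(frozen=True)
class Setting:
    index: int
    nGP: int
    h2: float
    Ne: int
    NumCross: int
    SelectSP: str
    CycleTime: int

    def levels(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("nGP", "h2", "Ne", "NumCross", "SelectSP", "CycleTime")
        }


@dataclass(frozen=True)
class FactorialDesign:
    replicates: int = 20
    base_seed: int = 0
    genome: GenomeParams = field(default_factory=GenomeParams)
    n_founders: int = 1000
    burn_in_generations: int = 100
    horizon: int = 10
    markers_per_chromosome: int | None = None  # None = full non-QTL panel
    gs_lambda: float | str | None = None  # None = REML each cycle

    def settings(self) -> list[Setting]:
        combos = itertools.product(*FACTOR_LEVELS.values())
        return [
            Setting(i, *combo) for i, combo in enumerate(combos)
        ]

    @classmethod
    def scaled_down(cls, base_seed: int = 0, replicates: int = 5) -> "FactorialDesign":
        """Reduced-cost sweep: fewer replicates, a downsampled GS marker
        panel and the heuristic fixed shrinkage ratio instead of REML."""
        return cls(
            replicates=replicates,
            base_seed=base_seed,
            markers_per_chromosome=50,
            gs_lambda="auto",
        )


@dataclass
class RunResult:
    setting: Setting
    replicate: int
    records: list[MetricsRecord]
    gain: float
    final_var_g: float
    final_accuracy: float

    @classmethod
    def from_records(
        cls, setting: Setting, replicate: int, records: list[MetricsRecord]
    ) -> "RunResult":
        by_year = {r.year: r for r in records}
        horizon = max(by_year)
        # 10-year gain measured from the unselected founder gametophyte
        # stage (year 1, genetic mean ~0 by trait scaling)
        return cls(
            setting=setting,
            replicate=replicate,
            records=records,
            gain=by_year[horizon].mean_g - by_year[1].mean_g,
            final_var_g=by_year[horizon].var_g,
            final_accuracy=by_year[horizon].accuracy,
        )


@dataclass
class FactorialResults:
    runs: list[RunResult]
    failures: list[dict] = field(default_factory=list)

    def to_run_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            row = {"setting": r.setting.index, **r.setting.levels(), "rep": r.replicate}
            row.update(
                gain=r.gain, final_varG=r.final_var_g, final_accuracy=r.final_accuracy
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_year_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            base = {"setting": r.setting.index, **r.setting.levels(), "rep": r.replicate}
            for rec in r.records:
                rows.append(
                    {
                        **base,
                        "year": rec.year,
                        "meanG": rec.mean_g,
                        "varG": rec.var_g,
                        "accuracy": rec.accuracy,
                        "new_cohort": rec.new_cohort,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sweep execution
# ---------------------------------------------------------------------------


def _founder_rng(design: FactorialDesign, ne: int, rep: int) -> np.random.Generator:
    ne_idx = FACTOR_LEVELS["Ne"].index(ne)
    return np.random.default_rng(
        np.random.SeedSequence(design.base_seed, spawn_key=(0, ne_idx, rep))
    )


def _scheme_rng(design: FactorialDesign, setting: Setting, rep: int):
    return np.random.default_rng(
        np.random.SeedSequence(design.base_seed, spawn_key=(1, setting.index, rep))
    )


def _founder_bundle(design: FactorialDesign, ne: int, rep: int, cache: dict):
    """Founders, downsampled marker panel and per-h2 traits for (Ne, rep)."""
    key = (ne, rep)
    if key in cache:
        return cache[key]
    rng = _founder_rng(design, ne, rep)
    founders = simulate_founders(
        FounderConfig(
            effective_population_size=ne,
            n_founders=design.n_founders,
            burn_in_generations=design.burn_in_generations,
        ),
        design.genome,
        rng,
    )
    markers = founders.marker_sites
    if design.markers_per_chromosome is not None:
        picked = []
        per_chr = design.genome.sites_per_chromosome - design.genome.qtl_per_chromosome
        markers_by_chr = markers.reshape(design.genome.n_chromosomes, per_chr)
        for c in range(design.genome.n_chromosomes):
            picked.append(
                np.sort(
                    rng.choice(
                        markers_by_chr[c],
                        size=min(design.markers_per_chromosome, per_chr),
                        replace=False,
                    )
                )
            )
        markers = np.concatenate(picked)
    # one effect vector shared across the two heritabilities: only the error
    # variance differs, which pairs the h2 contrast on a common trait
    base_trait = TraitModel.from_founders(
        founders.haplotypes, founders.qtl_sites, heritability=0.5, rng=rng
    )
    traits = {
        h2: dataclasses.replace(
            base_trait,
            heritability=h2,
            error_variance=error_variance_for_h2(h2),
        )
        for h2 in FACTOR_LEVELS["h2"]
    }
    cache[key] = (founders, markers, traits)
    return cache[key]


def _checkpoint_path(checkpoint_dir: Path, setting: Setting, rep: int) -> Path:
    return checkpoint_dir / f"run_s{setting.index:02d}_r{rep:03d}.json"


def _records_to_json(records: list[MetricsRecord]) -> list[dict]:
    return [dataclasses.asdict(r) for r in records]


def _records_from_json(payload: list[dict]) -> list[MetricsRecord]:
    return [MetricsRecord(**r) for r in payload]


def run_factorial(
    design: FactorialDesign,
    checkpoint_dir: str | Path | None = None,
    settings_filter: dict | None = None,
    progress: bool = False,
) -> FactorialResults:
    """Run the factorial sweep (embarrassingly parallel granularity).

    Results are a pure function of (design, base seed) and independent of
    execution order.  With ``checkpoint_dir`` each completed run is saved as
    a small JSON file and skipped on resume.  Individual run failures are
    recorded and the sweep continues.
    """
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
    settings = design.settings()
    if settings_filter:
        settings = [
            s
            for s in settings
            if all(getattr(s, k) == v for k, v in settings_filter.items())
        ]
    cache: dict = {}
    runs: list[RunResult] = []
    failures: list[dict] = []
    for setting in settings:
        for rep in range(design.replicates):
            if checkpoint_dir is not None:
                path = _checkpoint_path(checkpoint_dir, setting, rep)
                if path.exists():
                    payload = json.loads(path.read_text())
                    runs.append(
                        RunResult.from_records(
                            setting, rep, _records_from_json(payload["records"])
                        )
                    )
                    continue
            try:
                founders, markers, traits = _founder_bundle(
                    design, setting.Ne, rep, cache
                )
                cfg = SchemeConfig(
                    cycle_time=setting.CycleTime,
                    num_cross=setting.NumCross,
                    select_sp=setting.SelectSP,
                    n_gp=setting.nGP,
                    horizon=design.horizon,
                )
                records = run_scheme(
                    cfg,
                    founders,
                    traits[setting.h2],
                    _scheme_rng(design, setting, rep),
                    marker_sites=markers,
                    gs_lambda=design.gs_lambda,
                )
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                failures.append(
                    {"setting": setting.index, "rep": rep, "error": repr(exc)}
                )
                continue
            runs.append(RunResult.from_records(setting, rep, records))
            if checkpoint_dir is not None:
                path.write_text(
                    json.dumps(
                        {
                            "setting": setting.levels(),
                            "rep": rep,
                            "records": _records_to_json(records),
                        }
                    )
                )
            if progress:
                print(f"setting {setting.index:02d} rep {rep}: done", flush=True)
    return FactorialResults(runs=runs, failures=failures)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def gain_summary(results: FactorialResults | pd.DataFrame) -> pd.DataFrame:
    """Per-factor percent change in mean 10-year gain, averaged across all
    other factor combinations (reference vs intervention level)."""
    df = (
        results.to_run_frame()
        if isinstance(results, FactorialResults)
        else results
    )
    rows = []
    for factor, (ref, alt) in INTERVENTIONS.items():
        for level in (ref, alt):
            if not (df[factor] == level).any():
                raise ValueError(f"results lack level {level!r} of {factor}")
        mean_ref = df.loc[df[factor] == ref, "gain"].mean()
        mean_alt = df.loc[df[factor] == alt, "gain"].mean()
        pct = np.nan
        if mean_ref > 0:
            pct = 100.0 * (mean_alt - mean_ref) / mean_ref
        rows.append(
            {
                "factor": factor,
                "reference_level": ref,
                "intervention_level": alt,
                "mean_gain_reference": mean_ref,
                "mean_gain_intervention": mean_alt,
                "pct_change": pct,
            }
        )
    return pd.DataFrame(rows)


def replicate_gain_changes(results: FactorialResults | pd.DataFrame) -> pd.DataFrame:
    """Per-replicate percent gain changes for each intervention factor.

    Replicates share founder populations across settings, so the factor
    contrast within one replicate index is paired; the spread across
    replicates estimates the sampling error of the factor-level percent
    changes.
    """
    df = (
        results.to_run_frame()
        if isinstance(results, FactorialResults)
        else results
    )
    rows = []
    for rep in sorted(df["rep"].unique()):
        sub = gain_summary(df[df["rep"] == rep])
        for _, row in sub.iterrows():
            rows.append(
                {"rep": rep, "factor": row["factor"], "pct_change": row["pct_change"]}
            )
    return pd.DataFrame(rows)


def all_interventions_fold(
    results: FactorialResults | pd.DataFrame,
) -> dict:
    """Fold-change in mean gain: all four interventions vs baseline, per
    (Ne, h2) slice and averaged across slices."""
    df = (
        results.to_run_frame()
        if isinstance(results, FactorialResults)
        else results
    )
    base = {f: levels[0] for f, levels in INTERVENTIONS.items()}
    full = {f: levels[1] for f, levels in INTERVENTIONS.items()}

    def mask(frame, levels):
        m = np.ones(len(frame), dtype=bool)
        for k, v in levels.items():
            m &= frame[k] == v
        return m

    per_slice = {}
    for ne in sorted(df["Ne"].unique()):
        for h2 in sorted(df["h2"].unique()):
            sl = df[(df["Ne"] == ne) & (df["h2"] == h2)]
            g_base = sl.loc[mask(sl, base), "gain"].mean()
            g_full = sl.loc[mask(sl, full), "gain"].mean()
            per_slice[(ne, h2)] = g_full / g_base if g_base > 0 else np.nan
    values = [v for v in per_slice.values() if np.isfinite(v)]
    return {
        "per_slice": per_slice,
        "mean_fold": float(np.mean(values)) if values else np.nan,
    }


def anova_table(
    results: FactorialResults | pd.DataFrame,
    response: str = "gain",
    ne: int | None = None,
    h2: float | None = None,
) -> pd.DataFrame:
    """Fixed-effects ANOVA of a per-replicate response within one
    (Ne, h2) slice: 4 scheme main effects + 6 pairwise interactions.

    The slice must be balanced (classical sums of squares then coincide
    across types); F statistics are against the residual mean square.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = (
        results.to_run_frame()
        if isinstance(results, FactorialResults)
        else results.copy()
    )
    if ne is not None:
        df = df[df["Ne"] == ne]
    if h2 is not None:
        df = df[np.isclose(df["h2"], h2)]
    if df.empty:
        raise ValueError("no runs in the requested (Ne, h2) slice")
    counts = df.groupby(list(SCHEME_FACTORS), observed=True).size()
    if counts.nunique() != 1 or len(counts) != 16:
        raise ValueError(
            "ANOVA requires a balanced slice: all 16 scheme-factor cells "
            "with equal replication"
        )
    data = df.copy()
    data["y"] = data[response]
    formula = "y ~ (C(SelectSP) + C(NumCross) + C(CycleTime) + C(nGP)) ** 2"
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=1)
    table = table.rename(
        index=lambda name: name.replace("C(", "").replace(")", "")
    ).rename(index={"Residual": "Residuals"})
    table.index.name = "term"
    return table.rename(
        columns={"df": "Df", "sum_sq": "Sum Sq", "mean_sq": "Mean Sq", "F": "F", "PR(>F)": "P"}
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def trajectory_table(results: FactorialResults | pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged per-year meanG/varG/accuracy per setting."""
    df = (
        results.to_year_frame()
        if isinstance(results, FactorialResults)
        else results
    )
    keys = ["setting", *FACTOR_LEVELS.keys(), "year"]
    return (
        df.groupby(keys, observed=True)[["meanG", "varG", "accuracy"]]
        .mean()
        .reset_index()
    )


def report(results: FactorialResults, out_dir: str | Path) -> dict[str, Path]:
    """Write trajectory tables, the gain summary and trajectory figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    traj = trajectory_table(results)
    written["trajectories"] = out_dir / "metrics_by_year.csv"
    traj.to_csv(written["trajectories"], index=False)
    written["runs"] = out_dir / "metrics_by_run.csv"
    results.to_run_frame().to_csv(written["runs"], index=False)
    summary = gain_summary(results)
    written["gain_summary"] = out_dir / "gain_summary.csv"
    summary.to_csv(written["gain_summary"], index=False)

    for metric, label in [
        ("meanG", "genetic mean"),
        ("varG", "genetic variance"),
        ("accuracy", "GS accuracy"),
    ]:
        for ngp in sorted(traj["nGP"].unique()):
            fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
            for ax, (ne, h2) in zip(
                axes.ravel(),
                itertools.product(
                    sorted(traj["Ne"].unique()), sorted(traj["h2"].unique())
                ),
            ):
                panel = traj[
                    (traj["nGP"] == ngp)
                    & (traj["Ne"] == ne)
                    & (np.isclose(traj["h2"], h2))
                ]
                for (sel, nc, ct), grp in panel.groupby(
                    ["SelectSP", "NumCross", "CycleTime"], observed=True
                ):
                    ax.plot(
                        grp["year"],
                        grp[metric],
                        marker="o",
                        markersize=2.5,
                        label=f"{sel}/{nc}/{ct}yr",
                    )
                ax.set_title(f"Ne={ne}, h2={h2}")
                ax.set_xlabel("year")
                ax.set_ylabel(label)
            axes[0, 0].legend(fontsize=6, ncol=2)
            fig.suptitle(f"{label} of the GP population (nGP={ngp})")
            fig.tight_layout()
            path = out_dir / f"{metric}_nGP{ngp}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"{metric}_nGP{ngp}"] = path
    return written
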