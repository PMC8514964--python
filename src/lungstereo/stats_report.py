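"""Two-group statistics, report rendering and pipeline orchestration.

Inference follows conventional morphometry practice: per parameter, a
two-sided Student's t-test when both groups pass Shapiro-Wilk normality
(alpha = 0.05), otherwise the Mann-Whitney rank-sum test; significance
at p <= 0.05, no multiple-testing correction.  That mirrors the
published analysis this package reproduces and is recorded per row so
the choice is auditable; it is not a statistical endorsement.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import ROW_LABELS, AnimalEstimates, estimate_animal
from .phantom import (
    GroupPreset,
    build_lung_phantom,
    max_edema_airspace_fraction,
    min_packable_septal_thickness_um,
)
from .presets import get_preset
from .sampling import SamplingPlan

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str  # "t" | "rank-sum"
    significant: bool
    degenerate: bool = False


@dataclass
class GroupSummary:
    """Per-parameter mean/SD for two groups plus the test verdicts."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    means_a: dict[str, float]
    sds_a: dict[str, float]
    means_b: dict[str, float]
    sds_b: dict[str, float]
    tests: dict[str, TestResult]


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> TestResult:
    """Two-sided two-group comparison with normality-gated test choice."""
    a = np.asarray([v for v in values_a if not math.isnan(v)], float)
    b = np.asarray([v for v in values_b if not math.isnan(v)], float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TestResult(0.0, 1.0, "t", False, degenerate=True)
        return TestResult(math.inf, 0.0, "t", True, degenerate=True)

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue > ALPHA

    if _normal(a) and _normal(b):
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "rank-sum"
    p = float(res.pvalue)
    return TestResult(float(res.statistic), p, name, p <= ALPHA)


def summarize_group(estimates: Sequence[AnimalEstimates]) -> pd.DataFrame:
    """Arithmetic mean and sample SD per parameter (rows in table order)."""
    if not estimates:
        raise ValueError("no animals to summarize")
    keys = AnimalEstimates.keys()
    for i, est in enumerate(estimates):
        missing = [k for k in keys if not hasattr(est, k)]
        if missing:
            raise ValueError(f"animal {i} is missing parameter(s): {missing}")
    df = pd.DataFrame([e.as_dict() for e in estimates])
    if len(df) == 1:
        warnings.warn("single animal: SD reported as 0")
        sd = pd.Series(0.0, index=df.columns)
    else:
        sd = df.std(ddof=1)
    return pd.DataFrame({"mean": df.mean(), "sd": sd, "n": df.notna().sum()}).loc[keys]


def compare_summaries(
    estimates_a: Sequence[AnimalEstimates],
    estimates_b: Sequence[AnimalEstimates],
    name_a: str = "normoxia",
    name_b: str = "hyperoxia",
) -> GroupSummary:
    sum_a = summarize_group(estimates_a)
    sum_b = summarize_group(estimates_b)
    df_a = pd.DataFrame([e.as_dict() for e in estimates_a])
    df_b = pd.DataFrame([e.as_dict() for e in estimates_b])
    tests: dict[str, TestResult] = {}
    for key in AnimalEstimates.keys():
        va = df_a[key].dropna().tolist()
        vb = df_b[key].dropna().tolist()
        if len(va) >= 2 and len(vb) >= 2:
            tests[key] = compare_groups(va, vb)
    return GroupSummary(
        group_a=name_a,
        group_b=name_b,
        n_a=len(estimates_a),
        n_b=len(estimates_b),
        means_a=sum_a["mean"].to_dict(),
        sds_a=sum_a["sd"].to_dict(),
        means_b=sum_b["mean"].to_dict(),
        sds_b=sum_b["sd"].to_dict(),
        tests=tests,
    )


def render_table1(summary: GroupSummary) -> pd.DataFrame:
    """Morphometric report: one row per parameter, mean/SD per group,
    a star on group-B cells that differ significantly from group A."""
    rows = []
    for key, label in ROW_LABELS.items():
        t = summary.tests.get(key)
        star = "*" if (t is not None and t.significant) else ""
        rows.append(
            {
                "parameter": label,
                "key": key,
                f"{summary.group_a}_mean": summary.means_a.get(key, math.nan),
                f"{summary.group_a}_sd": summary.sds_a.get(key, math.nan),
                f"{summary.group_b}_mean": summary.means_b.get(key, math.nan),
                f"{summary.group_b}_sd": summary.sds_b.get(key, math.nan),
                "test": t.test if t else "",
                "p_value": t.p_value if t else math.nan,
                "significant": star,
            }
        )
    return pd.DataFrame(rows)


def format_table(table: pd.DataFrame, group_a: str, group_b: str) -> str:
    """Human-readable rendering of :func:`render_table1` output."""
    lines = [f"{'Parameter':<28}{group_a:>22}{group_b:>24}  test  p"]
    for _, r in table.iterrows():
        a = f"{r[f'{group_a}_mean']:.4g}/{r[f'{group_a}_sd']:.3g}"
        b = f"{r[f'{group_b}_mean']:.4g}/{r[f'{group_b}_sd']:.3g}{r['significant']}"
        p = "" if math.isnan(r["p_value"]) else f"{r['p_value']:.3g}"
        lines.append(f"{r['parameter']:<28}{a:>22}{b:>24}  {r['test']:<5} {p}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end simulation study configuration."""

    group_a: str = "normoxia"
    group_b: str = "hyperoxia"
    n_per_group: int = 8
    seed: int = 0
    nx: int = 256
    ny: int = 256
    voxel_um: float = 1.5
    mode: str = "closed_cell"
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        plan = SamplingPlan(**raw.pop("plan", {}))
        return cls(plan=plan, **raw)

    def to_yaml(self, path: str) -> None:
        import json

        import yaml

        raw = json.loads(json.dumps(dataclasses.asdict(self)))  # tuples -> lists
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PipelineResult:
    config: PipelineConfig
    estimates: dict[str, list[AnimalEstimates]]
    summary: GroupSummary
    table: pd.DataFrame

    def animals_frame(self) -> pd.DataFrame:
        rows = []
        for group, ests in self.estimates.items():
            for i, e in enumerate(ests):
                rows.append({"group": group, "animal": i, **e.as_dict()})
        return pd.DataFrame(rows)


def simulate_animal(
    preset: GroupPreset,
    seed: int,
    nx: int = 256,
    ny: int = 256,
    voxel_um: float = 1.5,
    plan: SamplingPlan | None = None,
    mode: str = "closed_cell",
) -> AnimalEstimates:
    """One animal: jitter the preset, build the lung, measure it."""
    rng = np.random.default_rng(seed)
    bio_seed, build_seed, measure_seed = rng.integers(0, 2**31 - 1, 3)
    animal = preset.jittered(np.random.default_rng(int(bio_seed)))
    # extreme downward thickness draws are capped at the packing floor:
    # a sphere lattice cannot represent septa thinner than near-touching
    # cavities allow
    floor = 1.02 * min_packable_septal_thickness_um(animal, voxel_um)
    if animal.septal_thickness_um < floor:
        animal = dataclasses.replace(animal, septal_thickness_um=floor)
    edema_cap = 0.9 * max_edema_airspace_fraction(animal)
    if animal.edema_airspace_fraction > edema_cap:
        animal = dataclasses.replace(animal, edema_airspace_fraction=edema_cap)
    lung = build_lung_phantom(
        animal, seed=int(build_seed), nx=nx, ny=ny, voxel_um=voxel_um, mode=mode
    )
    return estimate_animal(lung, plan, seed=int(measure_seed))


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Simulate and analyse a full two-group cohort.

    Fully reproducible from ``config.seed``; per-animal estimate CSVs,
    the group report and the realized configuration are written to
    ``config.outdir`` when set.
    """
    config = config or PipelineConfig()
    root = np.random.default_rng(config.seed)
    estimates: dict[str, list[AnimalEstimates]] = {}
    for group in (config.group_a, config.group_b):
        preset = get_preset(group)
        seeds = root.integers(0, 2**31 - 1, config.n_per_group)
        ests = []
        for s in seeds:
            try:
                ests.append(
                    simulate_animal(
                        preset,
                        int(s),
                        nx=config.nx,
                        ny=config.ny,
                        voxel_um=config.voxel_um,
                        plan=config.plan,
                        mode=config.mode,
                    )
                )
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"pipeline failed for group {group!r}, animal seed {s}: {exc}"
                ) from exc
        estimates[group] = ests

    summary = compare_summaries(
        estimates[config.group_a],
        estimates[config.group_b],
        config.group_a,
        config.group_b,
    )
    table = render_table1(summary)
    result = PipelineResult(config=config, estimates=estimates, summary=summary, table=table)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        result.animals_frame().to_csv(out / "animals.csv", index=False)
        table.to_csv(out / "report.csv", index=False)
        (out / "report.txt").write_text(
            format_table(table, config.group_a, config.group_b) + "\n"
        )
        config.to_yaml(str(out / "config.yaml"))
    return result
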