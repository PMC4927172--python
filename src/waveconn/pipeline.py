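"""End-to-end study orchestration in a model / results idiom.

:class:`CohortStudy` is built from a cohort (synthetic or loaded from a
manifest) and a :class:`RunConfig` describing the wavelet sweep;
``fit()`` executes decompose -> connectivity -> threshold -> metrics for
every cell of the sweep and returns a :class:`CohortStudyResults`
carrying the tidy result table plus the comparison battery: variation
statistics, DWT-vs-MODWT tests, filter-type sign tests,
repeated-measures length ANOVAs, sensitivity surfaces and the
classification sweep.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from waveconn import classify as _classify
from waveconn import stats as _stats
from waveconn.cohort import Cohort, CohortSpec, generate_cohort
from waveconn.connectivity import (
    partial_correlation_matrix,
    summary_weighted_metrics,
    wavelet_correlation_matrix,
)
from waveconn.filters import ADMISSIBLE, make_filter
from waveconn.graphs import METRIC_NAMES, compute_all_metrics
from waveconn.io import read_cohort
from waveconn.transforms import decompose_matrix

__all__ = ["RunConfig", "CohortStudy", "CohortStudyResults", "run_pipeline",
           "DEFAULT_SWEEP"]

#: The full filter sweep: D 2-20, LA 8-20, C 6-24.
DEFAULT_SWEEP = tuple(
    (family, length)
    for family, lengths in ADMISSIBLE.items()
    for length in lengths
)


@dataclass
class RunConfig:
    """What to compute: sweep axes, estimator and algorithm settings."""

    methods: tuple[str, ...] = ("MODWT", "DWT")
    sweep: tuple[tuple[str, int], ...] = DEFAULT_SWEEP
    scales: tuple[int, ...] = (1, 2, 3, 4)
    levels: int = 4
    density: float = 0.30
    threshold_mode: str = "strongest"
    estimator: str = "correlation"  # or "partial"
    use_details: bool = False
    exclude_boundary: bool = False
    graph_metrics: bool = True
    modularity_restarts: int = 20
    modularity_reducer: str = "mean"
    consensus_null_permutations: int = 20
    ridge: float = 0.0
    seed: int = 0
    output_dir: str | None = None
    use_cache: bool = True

    def validate(self) -> None:
        for family, length in self.sweep:
            if length not in ADMISSIBLE.get(family, ()):
                raise ValueError(f"inadmissible sweep cell {family}{length}")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        for m in self.methods:
            if m.upper() not in ("DWT", "MODWT"):
                raise ValueError(f"unknown method {m}")
        bad = [s for s in self.scales if not 1 <= s <= self.levels]
        if bad:
            raise ValueError(f"scales {bad} outside 1..levels")

    def cache_key(self, cohort: Cohort) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        h = hashlib.sha256(payload.encode())
        h.update(np.ascontiguousarray(cohort.data).tobytes())
        return h.hexdigest()[:16]


def _cell_seed(global_seed: int, *tags) -> int:
    """Deterministic per-cell substream seed below 2**31."""
    label = "|".join(str(t) for t in tags)
    return (int(global_seed) ^ zlib.crc32(label.encode())) % (2**31 - 1)


class CohortStudy:
    """A two-group cohort plus the wavelet sweep to run on it.

    Construct with :meth:`from_spec` (simulate), :meth:`from_manifest`
    (load delimited text) or directly from a :class:`Cohort`; call
    :meth:`fit` to obtain a :class:`CohortStudyResults`.
    """

    def __init__(self, cohort: Cohort, config: RunConfig | None = None):
        self.cohort = cohort
        self.config = config or RunConfig()

    @classmethod
    def from_spec(cls, spec: CohortSpec | None = None,
                  config: RunConfig | None = None, **spec_kwargs):
        spec = spec or CohortSpec(**spec_kwargs)
        return cls(generate_cohort(spec), config)

    @classmethod
    def from_manifest(cls, manifest_path, config: RunConfig | None = None):
        return cls(read_cohort(manifest_path), config)

    def fit(self, config: RunConfig | None = None,
            progress: bool = False) -> "CohortStudyResults":
        """Run the sweep and assemble the cohort result table."""
        cfg = config or self.config
        cfg.validate()
        cache_path = None
        if cfg.output_dir is not None:
            outdir = Path(cfg.output_dir)
            outdir.mkdir(parents=True, exist_ok=True)
            cache_path = outdir / f"results_{cfg.cache_key(self.cohort)}.tsv"
            if cfg.use_cache and cache_path.exists():
                table = pd.read_csv(cache_path, sep="\t")
                return CohortStudyResults(self.cohort, cfg, table)
        rows = []
        for method in cfg.methods:
            for family, length in cfg.sweep:
                filt = make_filter(family, length)
                for sid, group, ts in self.cohort.subjects():
                    try:
                        decomps = decompose_matrix(ts, filt, method,
                                                   cfg.levels)
                    except Exception as exc:
                        raise RuntimeError(
                            f"decomposition failed for subject={sid} "
                            f"cell={method}/{family}{length}"
                        ) from exc
                    for scale in cfg.scales:
                        rows.append(self._cell_row(
                            cfg, sid, group, method, family, length,
                            scale, decomps))
                if progress:
                    print(f"done {method} {family}{length}")
        table = pd.DataFrame(rows)
        if cache_path is not None:
            table.to_csv(cache_path, sep="\t", index=False)
        return CohortStudyResults(self.cohort, cfg, table)

    def _cell_row(self, cfg, sid, group, method, family, length, scale,
                  decomps) -> dict:
        try:
            if cfg.estimator == "partial":
                cm = partial_correlation_matrix(
                    decomps, scale, ridge=cfg.ridge,
                    use_details=cfg.use_details,
                    exclude_boundary=cfg.exclude_boundary)
            else:
                cm = wavelet_correlation_matrix(
                    decomps, scale, use_details=cfg.use_details,
                    exclude_boundary=cfg.exclude_boundary)
            cm.subject_id = sid
            row = {"subject_id": sid, "group": group, "method": method,
                   "family": family, "length": length, "scale": scale}
            if cfg.graph_metrics:
                rec = compute_all_metrics(
                    cm, density=cfg.density, mode=cfg.threshold_mode,
                    n_restarts=cfg.modularity_restarts,
                    seed=_cell_seed(cfg.seed, sid, method, family, length,
                                    scale),
                    reducer=cfg.modularity_reducer,
                    n_null_permutations=cfg.consensus_null_permutations,
                )
                row |= rec.as_dict()
            else:
                mean_corr, var_corr = summary_weighted_metrics(cm)
                row |= {"mean_corr": mean_corr, "var_corr": var_corr}
            return row
        except Exception as exc:
            raise RuntimeError(
                f"metric computation failed for subject={sid} "
                f"cell={method}/{family}{length} scale={scale}"
            ) from exc


class CohortStudyResults:
    """Result table of a fitted study plus the comparison battery."""

    def __init__(self, cohort: Cohort, config: RunConfig,
                 table: pd.DataFrame):
        self.cohort = cohort
        self.config = config
        self.table = table

    # -- method comparison (DWT vs MODWT) ---------------------------------

    def variation_table(self, metric: str = "mean_corr",
                        scale: int | None = None) -> pd.DataFrame:
        """Per-subject length-variation statistic for every sweep cell."""
        return _stats.variation_table(self.table, metric, scale)

    def method_variation_tests(self, metric: str = "mean_corr",
                               group: str | None = "control") -> pd.DataFrame:
        """Paired t-tests of the variation statistic, MODWT minus DWT.

        One row per (scale, family): subjects are paired across method,
        so a negative t means MODWT varies less over filter lengths.
        """
        if not {"DWT", "MODWT"} <= set(self.table["method"].unique()):
            raise ValueError("needs both DWT and MODWT in the fitted sweep")
        rows = []
        for scale in sorted(self.table["scale"].unique()):
            vt = self.variation_table(metric, scale=scale)
            if group is not None:
                vt = vt[vt["group"] == group]
            for family in sorted(vt["family"].unique()):
                sub = vt[vt["family"] == family]
                wide = sub.pivot_table(index="subject_id", columns="method",
                                       values="variation")
                res = _stats.paired_t_test(wide["MODWT"].to_numpy(),
                                           wide["DWT"].to_numpy())
                rows.append({"scale": scale, "family": family,
                             "metric": metric, "t": res.statistic,
                             "df": res.df, "p": res.p_value})
        return pd.DataFrame(rows)

    def method_variance_tests(self, group: str | None = "control"
                              ) -> pd.DataFrame:
        """Paired t-tests of var_corr averaged over lengths and filters.

        One row per scale comparing the per-subject average variance of
        correlation coefficients under DWT versus MODWT; positive t
        means DWT estimates are more variable.
        """
        sub = self.table
        if group is not None:
            sub = sub[sub["group"] == group]
        rows = []
        for scale in sorted(sub["scale"].unique()):
            s = sub[sub["scale"] == scale]
            wide = s.pivot_table(index="subject_id", columns="method",
                                 values="var_corr", aggfunc="mean")
            res = _stats.paired_t_test(wide["DWT"].to_numpy(),
                                       wide["MODWT"].to_numpy())
            rows.append({"scale": scale, "t": res.statistic, "df": res.df,
                         "p": res.p_value})
        return pd.DataFrame(rows)

    # -- filter-type comparison -------------------------------------------

    def filter_type_sign_tests(
        self,
        pairs=(("D", 6, "C", 6), ("D", 8, "LA", 8)),
        scale: int = 2,
        method: str = "MODWT",
        alpha: float = 0.05,
        group: str | None = "control",
        metrics: tuple[str, ...] | None = None,
    ) -> pd.DataFrame:
        """Sign tests between same-length filters, Bonferroni-corrected.

        For each (family A, length, family B) pair and each metric,
        tests whether the paired difference median across subjects is
        zero; the ``significant`` column applies the family-wise
        threshold over all tests performed here.
        """
        sub = self.table[(self.table["scale"] == scale)
                         & (self.table["method"] == method)]
        if group is not None:
            sub = sub[sub["group"] == group]
        metrics = metrics or [m for m in METRIC_NAMES if m in sub.columns]
        rows = []
        for fam_a, len_a, fam_b, len_b in pairs:
            a = sub[(sub["family"] == fam_a) & (sub["length"] == len_a)]
            b = sub[(sub["family"] == fam_b) & (sub["length"] == len_b)]
            a = a.set_index("subject_id").sort_index()
            b = b.set_index("subject_id").sort_index()
            for metric in metrics:
                res = _stats.sign_test(a[metric].to_numpy(),
                                       b[metric].to_numpy())
                rows.append({
                    "pair": f"{fam_a}{len_a}-vs-{fam_b}{len_b}",
                    "metric": metric, "n_positive": res.statistic,
                    "n_nonzero": res.df, "p": res.p_value,
                })
        out = pd.DataFrame(rows)
        out["significant"] = _stats.familywise_correct(
            out["p"].fillna(1.0).to_numpy(), alpha)
        return out

    # -- length effect ----------------------------------------------------

    def length_anova(self, metric: str, family: str, scale: int = 2,
                     method: str = "MODWT",
                     group: str | None = "control") -> _stats.TestResult:
        """Repeated-measures ANOVA of one metric over filter lengths."""
        return _stats.rm_anova_length(self.table, metric, family, scale,
                                      method=method, group=group)

    def length_anova_table(self, scale: int = 2, method: str = "MODWT",
                           group: str | None = "control") -> pd.DataFrame:
        """ANOVA F and p for every metric x family at one scale."""
        metrics = [m for m in METRIC_NAMES if m in self.table.columns]
        rows = []
        for family in sorted(self.table["family"].unique()):
            for metric in metrics:
                res = self.length_anova(metric, family, scale, method, group)
                rows.append({"family": family, "metric": metric,
                             "F": res.statistic, "df1": res.df[0],
                             "df2": res.df[1], "p": res.p_value})
        return pd.DataFrame(rows)

    # -- group differences ------------------------------------------------

    def sensitivity_surface(self, scale: int = 2,
                            method: str = "MODWT") -> pd.DataFrame:
        """-log10 p of control-vs-patient t-tests per (family, length, metric)."""
        metrics = [m for m in METRIC_NAMES if m in self.table.columns]
        return _stats.sensitivity_surface(self.table, scale, method, metrics)

    def classification_sweep(self, scale: int = 2, method: str = "MODWT",
                             n_folds: int = 6, n_trials: int = 10,
                             seed: int | None = None) -> pd.DataFrame:
        """Boosted-tree cross-validated reports per (family, length)."""
        return _classify.classification_sweep(
            self.table, scale=scale, method=method, n_folds=n_folds,
            n_trials=n_trials,
            seed=self.config.seed if seed is None else seed)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Plain-text overview of the fitted sweep."""
        t = self.table
        lines = [
            "CohortStudy results",
            "===================",
            f"subjects: {t['subject_id'].nunique()} "
            f"({(t.drop_duplicates('subject_id')['group'] == 'control').sum()}"
            f" control / "
            f"{(t.drop_duplicates('subject_id')['group'] == 'patient').sum()}"
            f" patient)",
            f"methods: {sorted(t['method'].unique())}",
            f"filters: {sorted({f + str(l) for f, l in zip(t['family'], t['length'])})}",
            f"scales: {sorted(t['scale'].unique())}",
            f"rows: {len(t)}",
            "",
            "mean metric values (MODWT, by scale):",
        ]
        metrics = [m for m in METRIC_NAMES if m in t.columns]
        piv = (t[t["method"] == "MODWT"]
               .groupby("scale")[metrics].mean().round(4))
        lines.append(piv.to_string())
        return "\n".join(lines)

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "result_table.tsv"
        self.table.to_csv(path, sep="\t", index=False)
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, default=str)
        return path


def run_pipeline(config: RunConfig, cohort: Cohort | None = None,
                 spec: CohortSpec | None = None,
                 progress: bool = False) -> CohortStudyResults:
    """One-call orchestration: simulate/load, sweep, persist.

    Provide an explicit ``cohort`` or a :class:`CohortSpec` to simulate
    (a default-spec cohort seeded from ``config.seed`` otherwise).
    Results are written to ``config.output_dir`` when set.
    """
    if cohort is None:
        spec = spec or CohortSpec(seed=config.seed)
        cohort = generate_cohort(spec)
    results = CohortStudy(cohort, config).fit(progress=progress)
    if config.output_dir is not None:
        results.save(config.output_dir)
    return results
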