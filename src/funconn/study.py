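"""End-to-end connectome study: model and results objects.

`ConnectomeStudy` is the modelling entry point: it is built from a
cohort (per-subject ROI time series plus a subject manifest, optionally
per-node morphometry), holds the analysis configuration, and `fit()`
executes the full pipeline — quality gating, conditioning, association
matrices, the density sweep of graph metrics, permutation group
contrasts with effect sizes, nodal FDR-corrected contrasts, hub maps,
covariate correlations and structure-function regressions — returning a
`StudyResults` object with a `summary()` table and writers for the
on-disk report.

The same machinery runs the primary group contrast and the
genotype-within-group contrasts; only the grouping column differs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .connectome import (AssociationMatrix, DensitySweep, binarize_at_density,
                         binarize_at_threshold, correlation_matrix)
from .hubs import HubSet, compare_hub_sets, identify_hubs
from .inference import (CovariateCorrelation, GroupComparison,
                        StructureFunctionFit, compare_metric, fdr_correct,
                        mann_whitney_u, spearman_correlation,
                        structure_function_regression)
from .metrics import MetricProfile, auc_over_densities, metric_profile
from .prep import NuisanceSet, RoiTimeSeries, apply_tsnr_gate, condition_series

__all__ = ["StudyConfig", "ConnectomeStudy", "StudyResults", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """All analysis knobs, with conventional resting-state defaults."""

    densities: tuple[float, ...] = DensitySweep().densities
    threshold_mode: str = "density"        # or "absolute" (r cutoffs)
    negatives: str = "exclude"             # or "absolute" (rank by |r|)
    n_perm: int = 1000
    n_null: int = 20
    n_rewires_per_edge: int = 10
    k_sd: float = 2.0
    tsnr_threshold: float | None = 100.0
    bandpass: tuple[float, float] | None = None
    stage_order: str = "regress_then_filter"
    group_col: str = "group"
    genotype_col: str | None = "genotype"
    covariates: tuple[str, ...] = ()
    region_sets: dict = field(default_factory=dict)
    modularity_restarts: int = 10
    compute_sigma: bool = True
    permutation_statistic: str = "mean"
    hub_criteria: tuple[str, ...] = ("degree", "betweenness")

    def __post_init__(self) -> None:
        DensitySweep(self.densities)  # validates ordering and range
        if self.threshold_mode not in ("density", "absolute"):
            raise ValueError("threshold_mode must be 'density' or 'absolute'")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("densities", "covariates", "hub_criteria", "bandpass"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


def _child_seed(base: int, *key: int) -> int:
    """Deterministic per-task seed below 2**31."""
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


class ConnectomeStudy:
    """A two-group connectome comparison, built from cohort data.

    Parameters
    ----------
    series : list of RoiTimeSeries
        One entry per subject in the manifest.
    manifest : DataFrame
        Must carry ``subject_id`` and the grouping column; genotype and
        covariate columns are used when configured.
    morphometry : DataFrame, optional
        Long table (subject_id, group, node, volume, thickness) enabling
        structure-function regressions.
    config : StudyConfig or dict, optional
    """

    def __init__(
        self,
        series: Sequence[RoiTimeSeries],
        manifest: pd.DataFrame,
        morphometry: pd.DataFrame | None = None,
        config: StudyConfig | dict | None = None,
        nuisance: dict[str, NuisanceSet] | None = None,
    ) -> None:
        if config is None:
            config = StudyConfig()
        elif isinstance(config, dict):
            config = StudyConfig.from_dict(config)
        self.config = config
        if "subject_id" not in manifest.columns:
            raise ValueError("manifest must have a subject_id column")
        by_id = {s.subject_id: s for s in series}
        missing = [sid for sid in manifest["subject_id"] if sid not in by_id]
        if missing:
            raise ValueError(f"missing time series for subjects: {missing}")
        self.manifest = manifest.reset_index(drop=True)
        self.series = [by_id[sid] for sid in self.manifest["subject_id"]]
        self.morphometry = morphometry
        self.nuisance = nuisance or {}

    @classmethod
    def from_cohort_dir(
        cls, path: str | Path, config: StudyConfig | dict | None = None
    ) -> "ConnectomeStudy":
        """Load a cohort directory written by the simulator or by hand.

        Expects ``manifest.csv`` plus one ``<subject_id>.tsv`` per
        manifest row; ``morphometry.tsv`` is picked up when present.
        """
        path = Path(path)
        manifest = pd.read_csv(path / "manifest.csv")
        missing = [sid for sid in manifest["subject_id"]
                   if not (path / f"{sid}.tsv").exists()]
        if missing:
            raise ValueError(
                f"manifest lists subjects with no series file: {missing}")
        series = [RoiTimeSeries.from_tsv(path / f"{sid}.tsv", subject_id=sid)
                  for sid in manifest["subject_id"]]
        morph = None
        if (path / "morphometry.tsv").exists():
            morph = pd.read_csv(path / "morphometry.tsv", sep="\t")
        return cls(series, manifest, morphometry=morph, config=config)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "StudyResults":
        """Run the full pipeline; fully reproducible under ``seed``."""
        cfg = self.config
        series, exclusions = self._prep(self.series)
        kept_ids = {s.subject_id for s in series}
        manifest = self.manifest[
            self.manifest["subject_id"].isin(kept_ids)].reset_index(drop=True)

        assoc = {s.subject_id: correlation_matrix(s) for s in series}
        profiles = self._sweep(assoc, manifest, seed)
        global_df, nodal_df = self._tidy(profiles, manifest)
        auc_df = self._aucs(global_df)
        nodal_auc = self._nodal_aucs(nodal_df)

        comparisons = self._global_contrasts(global_df, auc_df, manifest, seed)
        nodal_tests = self._nodal_contrasts(nodal_auc, manifest)
        hub_sets, hub_tables = self._hubs(assoc, manifest)
        covariate_corrs = self._covariates(auc_df, manifest)
        sf_fits = self._structure_function(nodal_auc, manifest)

        return StudyResults(
            config=cfg, seed=seed, manifest=manifest,
            exclusions=exclusions, global_metrics=global_df,
            nodal_metrics=nodal_df, auc=auc_df, nodal_auc=nodal_auc,
            comparisons=comparisons, nodal_tests=nodal_tests,
            hub_sets=hub_sets, hub_tables=hub_tables,
            covariate_correlations=covariate_corrs,
            structure_function=sf_fits)

    # ------------------------------------------------------------------
    def _prep(self, series: Sequence[RoiTimeSeries]
              ) -> tuple[list[RoiTimeSeries], list[dict]]:
        cfg = self.config
        exclusions: list[dict] = []
        kept = list(series)
        if cfg.tsnr_threshold is not None:
            kept, exclusions = apply_tsnr_gate(kept, cfg.tsnr_threshold)
            if not kept:
                raise ValueError("all subjects excluded by the tSNR gate")
        if cfg.bandpass is not None or self.nuisance:
            low, high = cfg.bandpass if cfg.bandpass is not None \
                else (None, None)
            kept = [
                condition_series(
                    s, nuisance=self.nuisance.get(s.subject_id),
                    low_cut_hz=low, high_cut_hz=high, order=cfg.stage_order)
                for s in kept]
        return kept, exclusions

    def _binarize(self, assoc: AssociationMatrix, d: float):
        if self.config.threshold_mode == "density":
            return binarize_at_density(assoc, d,
                                       negatives=self.config.negatives)
        return binarize_at_threshold(assoc, d)

    def _sweep(self, assoc: dict[str, AssociationMatrix],
               manifest: pd.DataFrame, seed: int
               ) -> dict[str, list[MetricProfile]]:
        cfg = self.config
        out: dict[str, list[MetricProfile]] = {}
        for si, sid in enumerate(manifest["subject_id"]):
            rows = []
            for di, d in enumerate(cfg.densities):
                graph = self._binarize(assoc[sid], d)
                rows.append(metric_profile(
                    graph,
                    n_null=cfg.n_null,
                    n_rewires_per_edge=cfg.n_rewires_per_edge,
                    seed=_child_seed(seed, si, di),
                    compute_sigma=cfg.compute_sigma,
                    modularity_restarts=cfg.modularity_restarts))
            out[sid] = rows
        return out

    def _tidy(self, profiles: dict[str, list[MetricProfile]],
              manifest: pd.DataFrame
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
        cfg = self.config
        info = manifest.set_index("subject_id")
        g_rows, n_rows = [], []
        for sid, profs in profiles.items():
            for d, prof in zip(cfg.densities, profs):
                for metric, value in prof.globals_dict().items():
                    g_rows.append({
                        "subject_id": sid,
                        "group": info.loc[sid, cfg.group_col],
                        "genotype": (info.loc[sid, cfg.genotype_col]
                                     if cfg.genotype_col in info.columns
                                     else ""),
                        "density": d, "metric": metric, "value": value})
                labels = self.series[0].roi_labels
                for ni, node in enumerate(labels):
                    n_rows.append({
                        "subject_id": sid, "density": d, "node": node,
                        "degree": prof.nodal_degree[ni],
                        "betweenness": prof.nodal_betweenness[ni]})
        return pd.DataFrame(g_rows), pd.DataFrame(n_rows)

    def _aucs(self, global_df: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for (sid, metric), sub in global_df.groupby(
                    ["subject_id", "metric"], sort=True):
                sub = sub.sort_values("density")
                rows.append({
                    "subject_id": sid, "metric": metric,
                    "group": sub["group"].iloc[0],
                    "genotype": sub["genotype"].iloc[0],
                    "auc": auc_over_densities(sub["value"].to_numpy(),
                                              sub["density"].to_numpy())})
        return pd.DataFrame(rows)

    def _nodal_aucs(self, nodal_df: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (sid, node), sub in nodal_df.groupby(["subject_id", "node"],
                                                 sort=True):
            sub = sub.sort_values("density")
            d = sub["density"].to_numpy()
            rows.append({
                "subject_id": sid, "node": node,
                "degree_auc": auc_over_densities(sub["degree"].to_numpy(), d),
                "betweenness_auc": auc_over_densities(
                    sub["betweenness"].to_numpy(), d)})
        return pd.DataFrame(rows)

    def _contrast_battery(self, global_df, auc_df, mask_a, mask_b,
                          labels, contrast, seed):
        cfg = self.config
        out = []
        for mi, metric in enumerate(MetricProfile.GLOBAL_METRICS):
            if not cfg.compute_sigma and metric == "sigma":
                continue
            g = global_df[global_df["metric"] == metric]
            piv = g.pivot_table(index="subject_id", columns="density",
                                values="value", sort=True)
            piv = piv[sorted(piv.columns)]
            a_ids = auc_df.loc[mask_a, "subject_id"].unique()
            b_ids = auc_df.loc[mask_b, "subject_id"].unique()
            am = auc_df[(auc_df["metric"] == metric)
                        & auc_df["subject_id"].isin(a_ids)]
            bm = auc_df[(auc_df["metric"] == metric)
                        & auc_df["subject_id"].isin(b_ids)]
            out.append(compare_metric(
                am.sort_values("subject_id")["auc"].to_numpy(),
                bm.sort_values("subject_id")["auc"].to_numpy(),
                piv.loc[sorted(a_ids)].to_numpy(),
                piv.loc[sorted(b_ids)].to_numpy(),
                cfg.densities, metric, labels=labels,
                statistic=cfg.permutation_statistic, n_perm=cfg.n_perm,
                seed=_child_seed(seed, 7, mi), contrast=contrast))
        return out

    def _global_contrasts(self, global_df, auc_df, manifest, seed
                          ) -> list[GroupComparison]:
        cfg = self.config
        groups = sorted(manifest[cfg.group_col].unique())
        if len(groups) != 2:
            raise ValueError(
                f"grouping column {cfg.group_col!r} must have exactly two "
                f"levels, found {groups}")
        ga, gb = groups
        comparisons = self._contrast_battery(
            global_df, auc_df,
            auc_df["group"] == ga, auc_df["group"] == gb,
            (str(ga), str(gb)), f"group:{ga}_vs_{gb}", seed)
        # genotype-within-group: identical machinery, different column
        if cfg.genotype_col and cfg.genotype_col in manifest.columns:
            for gi, grp in enumerate(groups):
                sub = manifest[manifest[cfg.group_col] == grp]
                levels = sorted(sub[cfg.genotype_col].unique())
                if len(levels) != 2:
                    continue
                la, lb = levels
                ids_a = set(sub.loc[sub[cfg.genotype_col] == la,
                                    "subject_id"])
                ids_b = set(sub.loc[sub[cfg.genotype_col] == lb,
                                    "subject_id"])
                if min(len(ids_a), len(ids_b)) < 2:
                    continue
                g_sub = global_df[global_df["subject_id"].isin(
                    ids_a | ids_b)]
                a_sub = auc_df[auc_df["subject_id"].isin(ids_a | ids_b)]
                comparisons += self._contrast_battery(
                    g_sub, a_sub,
                    a_sub["subject_id"].isin(ids_a),
                    a_sub["subject_id"].isin(ids_b),
                    (str(la), str(lb)),
                    f"genotype_within_{grp}:{la}_vs_{lb}",
                    seed + 101 + gi)
        return comparisons

    def _nodal_contrasts(self, nodal_auc, manifest) -> pd.DataFrame:
        """Per-node Mann-Whitney on centrality AUC, FDR over nodes."""
        cfg = self.config
        groups = sorted(manifest[cfg.group_col].unique())
        ga, gb = groups
        info = manifest.set_index("subject_id")[cfg.group_col]
        nodal = nodal_auc.assign(group=nodal_auc["subject_id"].map(info))
        rows = []
        for measure in ("degree_auc", "betweenness_auc"):
            stats_rows = []
            for node, sub in nodal.groupby("node", sort=True):
                va = sub.loc[sub["group"] == ga, measure].to_numpy()
                vb = sub.loc[sub["group"] == gb, measure].to_numpy()
                u, p = mann_whitney_u(va, vb)
                stats_rows.append((node, u, p,
                                   float(np.mean(va) - np.mean(vb))))
            p_raw = [r[2] for r in stats_rows]
            adjusted, reject = fdr_correct(p_raw)
            for (node, u, p, diff), p_adj, rej in zip(stats_rows, adjusted,
                                                      reject):
                rows.append({
                    "measure": measure, "node": node, "u": u, "p": p,
                    "p_fdr": float(p_adj), "significant": bool(rej),
                    "mean_diff": diff})
        return pd.DataFrame(rows)

    def _hubs(self, assoc, manifest):
        cfg = self.config
        sweep = DensitySweep(cfg.densities) \
            if cfg.threshold_mode == "density" else None
        groups = sorted(manifest[cfg.group_col].unique())
        hub_sets: dict[tuple[str, str], HubSet] = {}
        tables: dict[str, str] = {}
        if sweep is None:
            return hub_sets, tables
        for criterion in cfg.hub_criteria:
            for grp in groups:
                ids = manifest.loc[manifest[cfg.group_col] == grp,
                                   "subject_id"]
                mats = [assoc[sid] for sid in ids]
                hub_sets[(str(grp), criterion)] = identify_hubs(
                    mats, sweep, criterion=criterion, k_sd=cfg.k_sd,
                    group_id=str(grp), negatives=cfg.negatives)
            if len(groups) == 2:
                cmp = compare_hub_sets(hub_sets[(str(groups[0]), criterion)],
                                       hub_sets[(str(groups[1]), criterion)])
                tables[criterion] = cmp.to_table()
        return hub_sets, tables

    def _covariates(self, auc_df, manifest) -> list[CovariateCorrelation]:
        cfg = self.config
        out: list[CovariateCorrelation] = []
        info = manifest.set_index("subject_id")
        for cov in cfg.covariates:
            if cov not in info.columns:
                raise ValueError(f"covariate {cov!r} not in manifest")
            for grp in sorted(manifest[cfg.group_col].unique()):
                for metric in MetricProfile.GLOBAL_METRICS:
                    sub = auc_df[(auc_df["metric"] == metric)
                                 & (auc_df["group"] == grp)]
                    x = sub["auc"].to_numpy()
                    y = info.loc[sub["subject_id"], cov].to_numpy(dtype=float)
                    ok = np.isfinite(x) & np.isfinite(y)
                    if ok.sum() < 4:
                        continue
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        rho, p = spearman_correlation(x[ok], y[ok])
                    out.append(CovariateCorrelation(
                        metric=metric, covariate=cov, rho=rho, p=p,
                        group=str(grp), n=int(ok.sum())))
        return out

    def _structure_function(self, nodal_auc, manifest
                            ) -> list[dict]:
        cfg = self.config
        if self.morphometry is None or not cfg.region_sets:
            return []
        groups = sorted(manifest[cfg.group_col].unique())
        ga, gb = groups
        info = manifest.set_index("subject_id")[cfg.group_col]
        morph = self.morphometry[
            self.morphometry["subject_id"].isin(info.index)].copy()
        morph["group"] = morph["subject_id"].map(info)
        nodal = nodal_auc.assign(group=nodal_auc["subject_id"].map(info))
        deg_means = nodal.pivot_table(index="node", columns="group",
                                      values="degree_auc")
        y = deg_means[ga] - deg_means[gb]
        fits = []
        for struct in ("volume", "thickness"):
            if struct not in morph.columns:
                continue
            sm = morph.pivot_table(index="node", columns="group",
                                   values=struct)
            x = sm[ga] - sm[gb]
            for name, region in cfg.region_sets.items():
                fit = structure_function_regression(x, y, region)
                fits.append({"region_set": name, "structural": struct,
                             "centrality": "degree_auc", "fit": fit})
        return fits


@dataclass
class StudyResults:
    """Everything `ConnectomeStudy.fit` computed, plus report writers."""

    config: StudyConfig
    seed: int
    manifest: pd.DataFrame
    exclusions: list[dict]
    global_metrics: pd.DataFrame
    nodal_metrics: pd.DataFrame
    auc: pd.DataFrame
    nodal_auc: pd.DataFrame
    comparisons: list[GroupComparison]
    nodal_tests: pd.DataFrame
    hub_sets: dict[tuple[str, str], HubSet]
    hub_tables: dict[str, str]
    covariate_correlations: list[CovariateCorrelation]
    structure_function: list[dict]

    def comparison(self, metric: str,
                   contrast_prefix: str = "group") -> GroupComparison:
        for c in self.comparisons:
            if c.metric == metric and c.contrast.startswith(contrast_prefix):
                return c
        raise KeyError(f"no comparison for {metric!r} / {contrast_prefix!r}")

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            (la, (ma, sa)), (lb, (mb, sb)) = c.group_means_sds.items()
            rows.append({
                "contrast": c.contrast, "metric": c.metric,
                "mean_a": ma, "sd_a": sa, "mean_b": mb, "sd_b": sb,
                "auc_perm_p": c.auc_p, "u": c.u_stat, "u_p": c.u_p,
                "cliffs_delta": c.delta, "n_perm": c.n_perm,
                "min_density_p": float(np.nanmin(
                    list(c.per_density_p.values())))})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the fitted study."""
        lines = ["Connectome study summary",
                 "=" * 24,
                 f"subjects analysed : {len(self.manifest)}"
                 f" (excluded by tSNR gate: "
                 f"{sum(1 for e in self.exclusions if e['decision'] != 'keep')})",
                 f"densities         : {list(self.config.densities)}",
                 f"permutations      : {self.config.n_perm}", ""]
        df = self.comparisons_frame()
        for contrast, sub in df.groupby("contrast", sort=True):
            lines.append(f"[{contrast}]")
            lines.append(f"{'metric':<8}{'mean_a (sd)':>16}{'mean_b (sd)':>16}"
                         f"{'AUC perm p':>12}{'U p':>10}{'delta':>9}")
            for _, r in sub.iterrows():
                lines.append(
                    f"{r['metric']:<8}"
                    f"{r['mean_a']:>9.3f} ({r['sd_a']:.3f})"
                    f"{r['mean_b']:>9.3f} ({r['sd_b']:.3f})"
                    f"{r['auc_perm_p']:>12.4f}{r['u_p']:>10.4f}"
                    f"{r['cliffs_delta']:>9.3f}")
            lines.append("")
        for criterion, table in sorted(self.hub_tables.items()):
            lines.append(f"hubs ({criterion}):")
            lines.append(table)
            lines.append("")
        for cc in self.covariate_correlations:
            if np.isfinite(cc.p) and cc.p < 0.05:
                lines.append(
                    f"covariate {cc.covariate} vs {cc.metric} "
                    f"[{cc.group}]: rho={cc.rho:.2f}, p={cc.p:.3f}")
        for sf in self.structure_function:
            fit = sf["fit"]
            lines.append(
                f"structure-function [{sf['region_set']}, {sf['structural']}]"
                f": slope={fit.slope:.3f}, R2={fit.r2:.2f}, p={fit.p:.3f}")
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "n_subjects": int(len(self.manifest)),
            "exclusions": self.exclusions,
            "comparisons": [
                {
                    "contrast": c.contrast, "metric": c.metric,
                    "per_density_p": {f"{d:g}": p
                                      for d, p in c.per_density_p.items()},
                    "auc_p": c.auc_p, "u": c.u_stat, "u_p": c.u_p,
                    "cliffs_delta": c.delta,
                    "group_means_sds": {k: list(v) for k, v
                                        in c.group_means_sds.items()},
                    "n_perm": c.n_perm,
                } for c in self.comparisons],
            "hubs": {f"{g}|{crit}": hs.to_dict()
                     for (g, crit), hs in self.hub_sets.items()},
            "covariate_correlations": [asdict(cc) for cc
                                       in self.covariate_correlations],
            "structure_function": [
                {"region_set": sf["region_set"],
                 "structural": sf["structural"],
                 "centrality": sf["centrality"],
                 "slope": sf["fit"].slope, "intercept": sf["fit"].intercept,
                 "r2": sf["fit"].r2, "p": sf["fit"].p,
                 "n_nodes": sf["fit"].n_nodes}
                for sf in self.structure_function],
            "nodal_significant": self.nodal_tests[
                self.nodal_tests["significant"]].to_dict("records"),
        }

    def save(self, out_dir: str | Path) -> Path:
        """Write report.json and the tidy TSV tables; deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_report_dict(), indent=2, sort_keys=True))
        self.global_metrics.to_csv(out / "global_metrics.tsv", sep="\t",
                                   index=False)
        self.nodal_metrics.to_csv(out / "nodal_metrics.tsv", sep="\t",
                                  index=False)
        self.comparisons_frame().to_csv(out / "comparisons.tsv", sep="\t",
                                        index=False)
        (out / "hubs.json").write_text(json.dumps(
            {f"{g}|{c}": hs.to_dict()
             for (g, c), hs in self.hub_sets.items()},
            indent=2, sort_keys=True))
        (out / "run_log.json").write_text(json.dumps(
            {"seed": self.seed, "config": self.config.to_dict(),
             "exclusions": self.exclusions}, indent=2, sort_keys=True))
        return out


def run_study(
    cohort_dir: str | Path,
    config: StudyConfig | dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> StudyResults:
    """Load a cohort directory, fit the study, optionally write reports."""
    model = ConnectomeStudy.from_cohort_dir(cohort_dir, config=config)
    results = model.fit(seed=seed)
    if out_dir is not None:
        results.save(out_dir)
    return results
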