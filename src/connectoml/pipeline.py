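"""End-to-end orchestration: simulate -> networks -> metrics -> selection ->
classification -> report.

Stages are plain functions over in-memory objects; :func:`run_pipeline` wires
them in analysis order, writes every artifact under the output directory and
returns the report dictionary.  Everything is deterministic given the config
seed (recorded, with the config hash, in the report provenance block).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from connectoml import __version__, io, mklsvm, netbuild, select, syncon
from connectoml import gmetrics
from connectoml.errors import ConfigurationError, DataError

log = logging.getLogger("connectoml")

GLOBAL_NAMES = list(gmetrics.GLOBAL_METRIC_NAMES)
NODAL_NAMES = list(gmetrics.NODAL_METRIC_NAMES)


@dataclass
class RunConfig:
    """Every knob of the pipeline; defaults give the scaled-down demo."""

    mode: str = "synthetic"  # or "user"
    # synthetic cohort
    n_patients: int = 30
    n_controls: int = 30
    n_rois: int = 60
    n_timepoints: int = 120
    n_modules: int = 6
    edge_effect: float = 0.8
    noise_sd: float = 0.8
    n_affected_edges: int = 25
    n_hubs: int = 4
    # user mode
    manifest_path: str = ""
    timeseries_dir: str = ""
    node_table_path: str = ""
    # sparsity grid
    grid_start: float = 0.02
    grid_stop: float = 0.50
    grid_step: float = 0.01
    # graph metrics
    n_random: int = 3
    # NBS
    nbs_primary_p: float = 0.01
    nbs_nperm: int = 200
    nbs_top_k: int = 100
    # group-LASSO
    lasso_lam: float = 1.0
    lasso_q: int = 2
    # MKL
    beta_step: float = 0.5
    c_exponents: tuple[int, ...] = (-5, -3, -1, 1, 3, 5)
    combos: tuple[str, ...] = ("C", "G", "N", "C+G+N", "CGN")
    scalar_view: str = ""
    # misc
    seed: int = 0
    out_dir: str = "connectoml_out"
    write_timeseries: bool = True
    write_long_metrics: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "user"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "user":
            for name in ("manifest_path", "timeseries_dir", "node_table_path"):
                p = getattr(self, name)
                if not p or not Path(p).exists():
                    raise ConfigurationError(f"{name} does not exist: {p!r}")
        netbuild.sparsity_grid(self.grid_start, self.grid_stop, self.grid_step)
        if self.n_random < 1:
            raise ConfigurationError("n_random must be >= 1")

    def c_grid(self) -> tuple[float, ...]:
        return tuple(2.0**e for e in self.c_exponents)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_exponents"] = list(self.c_exponents)
        d["combos"] = list(self.combos)
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # analysis-irrelevant
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a plain `key = value` config file; overrides win."""
        values: dict = {}
        defaults = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"{path}: line {lineno}: expected key = value")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if not hasattr(defaults, key):
                    raise ConfigurationError(f"{path}: line {lineno}: unknown key {key!r}")
                values[key] = _coerce(val, getattr(defaults, key))
        values.update(overrides)
        return cls(**values)


def _coerce(text: str, default):
    if isinstance(default, bool):
        return text.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    if isinstance(default, tuple):
        parts = [p.strip() for p in text.split(",") if p.strip()]
        if default and isinstance(default[0], int):
            return tuple(int(p) for p in parts)
        return tuple(parts)
    return text


# ---------------------------------------------------------------------------
# stages


def load_or_simulate(config: RunConfig) -> syncon.TimeSeriesCohort:
    if config.mode == "synthetic":
        spec = syncon.default_spec(
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            n_rois=config.n_rois,
            n_timepoints=config.n_timepoints,
            n_modules=config.n_modules,
            edge_effect=config.edge_effect,
            noise_sd=config.noise_sd,
            n_affected_edges=config.n_affected_edges,
            n_hubs=config.n_hubs,
            seed=config.seed,
        )
        return syncon.generate_cohort(spec)
    manifest = io.read_manifest(config.manifest_path)
    data = []
    for sid in manifest["subject_id"]:
        path = Path(config.timeseries_dir) / f"{sid}.tsv"
        if not path.exists():
            raise DataError(f"missing time-series file for subject {sid}: {path}")
        data.append(io.read_timeseries_tsv(path))
    return syncon.TimeSeriesCohort(
        subject_ids=list(manifest["subject_id"]),
        data=data,
        labels=manifest["label"].to_numpy(),
        covariates=manifest,
        truth=None,
    )


def stage_networks(cohort: syncon.TimeSeriesCohort) -> list[netbuild.ConnectivityMatrix]:
    """Per-subject Pearson connectivity with negatives zeroed."""
    return [
        netbuild.zero_negatives(netbuild.pearson_adjacency(ts)) for ts in cohort.data
    ]


def _safe_threshold_metrics(
    A: np.ndarray, n_random: int, seed_seq: list[int]
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    n = A.shape[0]
    if int(A.sum()) == 0:  # edgeless: everything zero by convention
        glob = {name: 0.0 for name in GLOBAL_NAMES}
        nod = {name: np.zeros(n) for name in NODAL_NAMES}
        return glob, nod
    part = gmetrics.greedy_modules(A)
    seed = int(np.random.SeedSequence(seed_seq).generate_state(1)[0])
    glob = gmetrics.global_metrics(
        A, n_random=n_random, seed=seed, partition=part
    )
    nod = gmetrics.nodal_metrics(A, P=part)
    return glob, nod


def stage_metrics(
    conns: list[netbuild.ConnectivityMatrix], config: RunConfig
) -> dict:
    """Threshold-resolved metrics plus their grid-AUC summaries.

    Returns global AUC features (n_subjects x 7), nodal AUC features
    (n_subjects x n_rois*7, metric-major per node), and the long-format
    records.  Undefined normalized values (gamma/lambda/sigma on degenerate
    nulls) contribute 0 to the AUC sum.
    """
    grid = netbuild.sparsity_grid(config.grid_start, config.grid_stop, config.grid_step)
    n_grid = len(grid)
    n_sub = len(conns)
    n_rois = conns[0].n_rois
    global_curves = np.zeros((n_sub, n_grid, len(GLOBAL_NAMES)))
    nodal_curves = np.zeros((n_sub, n_grid, n_rois, len(NODAL_NAMES)))
    for si, C in enumerate(conns):
        stack = netbuild.build_stack(C, config.grid_start, config.grid_stop, config.grid_step)
        for ti, A in enumerate(stack.networks):
            glob, nod = _safe_threshold_metrics(
                A, config.n_random, [config.seed, 1000 + si, ti]
            )
            for gi, name in enumerate(GLOBAL_NAMES):
                global_curves[si, ti, gi] = glob[name]
            for ni, name in enumerate(NODAL_NAMES):
                nodal_curves[si, ti, :, ni] = nod[name]
    global_curves = np.nan_to_num(global_curves, nan=0.0)
    global_auc = global_curves.sum(axis=1)  # threshold-AUC = sum over grid
    nodal_auc = nodal_curves.sum(axis=1).reshape(n_sub, n_rois * len(NODAL_NAMES))
    return {
        "grid": grid,
        "global_auc": global_auc,
        "nodal_auc": nodal_auc,
        "global_curves": global_curves,
        "nodal_curves": nodal_curves,
    }


def nodal_feature_groups(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """(roi group id, metric id) per nodal AUC feature, node-major order."""
    group_ids = np.repeat(np.arange(n_rois), len(NODAL_NAMES))
    metric_ids = np.tile(np.arange(len(NODAL_NAMES)), n_rois)
    return group_ids, metric_ids


def stage_select(
    conns: list[netbuild.ConnectivityMatrix],
    metrics: dict,
    cohort: syncon.TimeSeriesCohort,
    config: RunConfig,
) -> dict:
    """Edge statistics + NBS and group-LASSO selection; assemble views."""
    n_rois = conns[0].n_rois
    ii, jj = np.triu_indices(n_rois, k=1)
    edge_weights = np.stack([C.values[ii, jj] for C in conns])
    edge_z = netbuild.fisher_z(edge_weights)
    y = cohort.y()

    # covariate residualization before any group statistics / permutation
    edge_resid = select.regress_covariates(edge_z, cohort.covariates)
    global_resid = select.regress_covariates(metrics["global_auc"], cohort.covariates)
    nodal_resid = select.regress_covariates(metrics["nodal_auc"], cohort.covariates)

    g1, g2 = y == 1, y == -1
    t_vals = select._vectorized_t(edge_resid, g1, g2)
    p_vals = 2.0 * _stats.t.sf(np.abs(t_vals), int(g1.sum() + g2.sum() - 2))
    p_adj = select.fdr_bh(p_vals)

    nbs_res = select.nbs(
        edge_resid,
        y,
        n_rois,
        primary_p=config.nbs_primary_p,
        nperm=config.nbs_nperm,
        seed=config.seed + 101,
        top_k=config.nbs_top_k,
    )
    pair_index = {(int(a), int(b)): k for k, (a, b) in enumerate(zip(ii, jj))}
    top_cols = [pair_index[e] for e in nbs_res.top_edges]
    connections_view = edge_resid[:, top_cols]

    group_ids, metric_ids = nodal_feature_groups(n_rois)
    Xn, _, _ = netbuild.zscore_columns(nodal_resid)
    G = select.GroupedFeatureMatrix(X=Xn, group_ids=group_ids, metric_ids=metric_ids, y=y)
    model = select.group_lasso_logistic(G, lam=config.lasso_lam, q=config.lasso_q)
    selected_rois = sorted(model.selected_groups())
    feature_mask = model.W != 0
    if not feature_mask.any():
        warnings.warn(
            "group-LASSO selected no features; falling back to all nodal features",
            stacklevel=2,
        )
        feature_mask = np.ones_like(feature_mask)
    nodal_view = nodal_resid[:, feature_mask]

    views: dict[str, np.ndarray] = {
        "connections": connections_view,
        "global": global_resid,
        "nodal": nodal_view,
    }
    if config.scalar_view:
        if config.scalar_view not in cohort.covariates.columns:
            raise DataError(f"scalar view column missing: {config.scalar_view!r}")
        views["scalar"] = cohort.covariates[config.scalar_view].to_numpy(float)[:, None]

    return {
        "edge_t": t_vals,
        "edge_p": p_vals,
        "edge_p_fdr": p_adj,
        "n_significant_edges": int((p_vals < config.nbs_primary_p).sum()),
        "n_fdr_edges": int((p_adj < 0.05).sum()),
        "nbs": nbs_res,
        "lasso_model": model,
        "selected_rois": selected_rois,
        "per_metric_counts": select.count_selected_per_metric(model, metric_ids).tolist(),
        "views": views,
    }


_COMBO_VIEWS = {
    "C": ("connections",),
    "G": ("global",),
    "N": ("nodal",),
    "H": ("scalar",),
    "CG": ("connections", "global"),
    "CN": ("connections", "nodal"),
    "GN": ("global", "nodal"),
    "CGN": ("connections", "global", "nodal"),
    "CH": ("connections", "scalar"),
    "GH": ("global", "scalar"),
    "NH": ("nodal", "scalar"),
    "CGNH": ("connections", "global", "nodal", "scalar"),
}


def stage_classify(views: dict[str, np.ndarray], y: np.ndarray, config: RunConfig) -> dict:
    """Nested-LOOCV MKL for every requested view combination."""
    results: dict[str, mklsvm.MKLResult] = {}
    for combo in config.combos:
        if combo == "C+G+N":
            feats = {"concat": _concat_views(views, ("connections", "global", "nodal"))}
            beta_grid = [(1.0,)]
        else:
            names = _COMBO_VIEWS.get(combo)
            if names is None:
                raise ConfigurationError(f"unknown view combination {combo!r}")
            missing = [nm for nm in names if nm not in views]
            if missing:
                raise ConfigurationError(f"combo {combo}: missing views {missing}")
            feats = {nm: views[nm] for nm in names}
            beta_grid = (
                [(1.0,)]
                if len(names) == 1
                else mklsvm.beta_simplex_grid(len(names), step=config.beta_step)
            )
        results[combo] = mklsvm.loocv_mkl(
            feats, y, beta_grid=beta_grid, C_grid=config.c_grid()
        )
    return results


def _concat_views(views: dict[str, np.ndarray], names: tuple[str, ...]) -> np.ndarray:
    # per-view standardization before concatenation
    parts = []
    for nm in names:
        Xs, _, _ = netbuild.zscore_columns(views[nm])
        parts.append(Xs)
    return np.hstack(parts)


def demographics_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-variable group statistics: pooled t for continuous, chi-square for sex."""
    for col in ("label", "age", "sex", "education"):
        if col not in manifest.columns:
            raise DataError(f"manifest missing column {col!r}")
    pat = manifest[manifest["label"] == syncon.PATIENT]
    con = manifest[manifest["label"] == syncon.CONTROL]
    rows = []
    continuous = ["age", "education"] + [
        c
        for c in manifest.columns
        if c not in ("subject_id", "label", "age", "sex", "education")
        and pd.api.types.is_numeric_dtype(manifest[c])
    ]
    table = np.array(
        [
            [(pat["sex"] == "M").sum(), (pat["sex"] == "F").sum()],
            [(con["sex"] == "M").sum(), (con["sex"] == "F").sum()],
        ]
    )
    chi2, p = select.chi_square_2x2(table)
    rows.append(
        {
            "variable": "sex",
            "patient": f"{table[0, 0]}/{table[0, 1]}",
            "control": f"{table[1, 0]}/{table[1, 1]}",
            "statistic": chi2,
            "p": p,
            "test": "chi-square",
        }
    )
    for col in continuous:
        a = pat[col].to_numpy(float)
        b = con[col].to_numpy(float)
        if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = select.two_sample_t(a, b)
        rows.append(
            {
                "variable": col,
                "patient": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                "control": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "statistic": t,
                "p": p,
                "test": "t-test",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the end-to-end run


def run_pipeline(config: RunConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        cohort = load_or_simulate(config)
        io.write_manifest(out / "manifest.tsv", cohort.covariates)
        if cohort.truth is not None:
            io.write_node_table(out / "node_table.tsv", np.asarray(cohort.truth.module_assignment))
            for name, df in syncon.export_truth(cohort).items():
                io.write_table(out / f"truth_{name}.tsv", df)
        if config.write_timeseries:
            ts_dir = out / "timeseries"
            ts_dir.mkdir(exist_ok=True)
            for sid, mat in zip(cohort.subject_ids, cohort.data):
                io.write_timeseries_tsv(ts_dir / f"{sid}.tsv", mat)
        timings["simulate"] = time.perf_counter() - t0
        log.info("cohort ready: %d subjects, %d ROIs", cohort.n_subjects, cohort.n_rois)

        t0 = time.perf_counter()
        conns = stage_networks(cohort)
        conn_dir = out / "connectivity"
        conn_dir.mkdir(exist_ok=True)
        for sid, C in zip(cohort.subject_ids, conns):
            io.write_matrix_tsv(conn_dir / f"{sid}.tsv", C.values)
        timings["networks"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        metrics = stage_metrics(conns, config)
        _write_metric_tables(out, cohort, metrics, config)
        timings["metrics"] = time.perf_counter() - t0
        log.info("metrics done in %.1fs", timings["metrics"])

        t0 = time.perf_counter()
        selection = stage_select(conns, metrics, cohort, config)
        nbs_res = selection["nbs"]
        io.write_json(
            out / "nbs_components.json",
            {
                "primary_p": nbs_res.primary_p,
                "nperm": nbs_res.nperm,
                "components": [
                    {"edges": comp, "size": len(comp), "p": p}
                    for comp, p in zip(nbs_res.components, nbs_res.component_p)
                ],
                "top_edges": nbs_res.top_edges,
            },
        )
        _write_selected_manifest(out, selection, conns[0].n_rois)
        timings["select"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        results = stage_classify(selection["views"], cohort.y(), config)
        timings["classify"] = time.perf_counter() - t0
        log.info("classification done in %.1fs", timings["classify"])

        demo = demographics_table(cohort.covariates)
        io.write_table(out / "demographics.tsv", demo)

        performance = {}
        for combo, res in results.items():
            performance[combo] = {
                "accuracy": res.metrics["accuracy"],
                "sensitivity": res.metrics["sensitivity"],
                "specificity": res.metrics["specificity"],
                "auc": res.auc,
                "mean_betas": np.mean(np.array(res.fold_betas), axis=0).tolist(),
                "fold_C": res.fold_C,
            }
            io.write_json(
                out / f"mkl_{combo.replace('+', '_')}.json",
                {
                    "betas": [list(b) for b in res.fold_betas],
                    "C": res.fold_C,
                    "decisions": res.decisions,
                    "labels": res.y,
                    "confusion": asdict(res.confusion),
                    "auc": res.auc,
                },
            )
            np.savetxt(
                out / f"roc_{combo.replace('+', '_')}.tsv",
                res.roc_points,
                delimiter="\t",
                header="fpr\ttpr",
                comments="",
            )

        report = {
            "demographics": demo.to_dict(orient="records"),
            "network": {
                "n_subjects": cohort.n_subjects,
                "n_rois": cohort.n_rois,
                "n_thresholds": len(metrics["grid"]),
            },
            "selection": {
                "n_significant_edges": selection["n_significant_edges"],
                "n_fdr_edges": selection["n_fdr_edges"],
                "nbs_component_sizes": [len(c) for c in nbs_res.components],
                "nbs_component_p": nbs_res.component_p,
                "n_selected_rois": len(selection["selected_rois"]),
                "per_metric_counts": selection["per_metric_counts"],
            },
            "performance": performance,
            "provenance": {
                "config_hash": config.hash(),
                "seed": config.seed,
                "version": __version__,
                "timings_s": {k: round(v, 2) for k, v in timings.items()},
            },
        }
        io.write_json(out / "report.json", report)
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


def _write_metric_tables(out: Path, cohort, metrics: dict, config: RunConfig) -> None:
    n_rois = cohort.n_rois
    wide_cols = {}
    for gi, name in enumerate(GLOBAL_NAMES):
        wide_cols[f"global_{name}_auc"] = metrics["global_auc"][:, gi]
    group_ids, metric_ids = nodal_feature_groups(n_rois)
    for f in range(metrics["nodal_auc"].shape[1]):
        wide_cols[f"roi{group_ids[f]:03d}_{NODAL_NAMES[metric_ids[f]]}_auc"] = metrics[
            "nodal_auc"
        ][:, f]
    wide = pd.DataFrame({"subject_id": cohort.subject_ids} | wide_cols)
    io.write_table(out / "metrics_auc_wide.tsv", wide)
    if config.write_long_metrics:
        grid = metrics["grid"]
        recs = []
        for si, sid in enumerate(cohort.subject_ids):
            for ti, s in enumerate(grid):
                for gi, name in enumerate(GLOBAL_NAMES):
                    recs.append((sid, round(float(s), 4), name, "global", metrics["global_curves"][si, ti, gi]))
        io.write_table(
            out / "metrics_global_long.tsv",
            pd.DataFrame(recs, columns=["subject_id", "sparsity", "metric", "node_or_global", "value"]),
        )


def _write_selected_manifest(out: Path, selection: dict, n_rois: int) -> None:
    model = selection["lasso_model"]
    group_ids, metric_ids = nodal_feature_groups(n_rois)
    nz = np.flatnonzero(model.W)
    df = pd.DataFrame(
        {
            "roi_id": group_ids[nz],
            "metric": [NODAL_NAMES[metric_ids[f]] for f in nz],
            "weight": model.W[nz],
        }
    )
    io.write_table(out / "selected_features.tsv", df)
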