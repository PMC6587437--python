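"""End-to-end orchestration: simulate -> connect -> detect -> metrics ->
compare -> stats -> classify, with seeded determinism and file reports.

Every stage writes the plain-text formats declared by its module (TSV time
series, CSV matrices/tables, TSV partitions, JSON reports), so any stage
can be re-run from intermediates.  All randomness flows from one root seed
through named substreams; given (config, seed) the output bundle is
byte-for-byte reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import Cohort, SyntheticSpec, generate_cohort, read_cohort as _read_ts_cohort
from .connectivity import (
    ConnectivityMatrix, binarize, group_average, pearson_connectivity,
    read_matrix_csv, write_matrix_csv,
)
from .detection import detect_communities, write_partition_tsv
from .metrics import METRIC_NAMES, compute_all
from .comparison import group_permutation_test, nodal_permutation_test
from .group_stats import metric_group_table, kde_table
from .classify import FeatureTable, cross_validate, rfe_rank

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(1, 10))


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    synthetic: SyntheticSpec | None = None
    timeseries_manifest: str | None = None
    connectivity_manifest: str | None = None
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_permutations_global: int = 50_000
    n_permutations_nodal: int = 10_000
    cv_schemes: tuple[str, ...] = ("loo",)
    classifiers: tuple[str, ...] = ("lda", "knn")
    k_neighbors: int = 5
    run_nodal: bool = True
    run_rfe: bool = True
    seed: int = 0
    out_dir: str = "commpat_run"

    def __post_init__(self) -> None:
        self.thresholds = tuple(float(t) for t in self.thresholds)
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ValueError("thresholds must be sorted and unique")
        if not all(0.1 <= t <= 0.9 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0.1, 0.9]")
        if self.n_permutations_global < 1 or self.n_permutations_nodal < 1:
            raise ValueError("permutation counts must be >= 1")
        sources = [self.synthetic, self.timeseries_manifest, self.connectivity_manifest]
        if sum(s is not None for s in sources) != 1:
            raise ValueError("exactly one input source must be set")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if raw.get("synthetic") is not None and not isinstance(raw["synthetic"], SyntheticSpec):
            raw["synthetic"] = SyntheticSpec.from_dict(raw["synthetic"])
        for key in ("thresholds", "cv_schemes", "classifiers"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _substream_seed(root: int, *tags: int) -> int:
    ss = np.random.SeedSequence(entropy=root, spawn_key=tuple(tags))
    return int(ss.generate_state(1)[0])


def read_cohort(manifest_path: str | Path, kind: str = "timeseries"):
    """Load either a time-series cohort or a set of connectivity matrices."""
    if kind == "timeseries":
        return _read_ts_cohort(manifest_path)
    if kind == "connectivity":
        manifest_path = Path(manifest_path)
        manifest = pd.read_csv(manifest_path)
        required = {"subject_id", "group", "path"}
        if not required.issubset(manifest.columns):
            raise ValueError(f"{manifest_path}: manifest needs columns {sorted(required)}")
        mats, labels_ref = [], None
        for row in manifest.itertuples(index=False):
            m = read_matrix_csv(manifest_path.parent / row.path)
            m.subject_id = str(row.subject_id)
            if labels_ref is None:
                labels_ref = m.roi_labels
            elif m.roi_labels != labels_ref:
                raise ValueError(f"{row.path}: ROI labels differ across subjects")
            mats.append((m, str(row.group)))
        return mats
    raise ValueError(f"unknown cohort kind {kind!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to out_dir.

    Returns a dict of the in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        conn, labels, subject_ids = _load_connectivity(config, out)
        groups = sorted(set(labels))
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, got {groups}")

        stage = "group_average"
        averages = {
            g: group_average([c for c, lab in zip(conn, labels) if lab == g])
            for g in groups
        }
        for g, avg in averages.items():
            write_matrix_csv(avg, out / f"group_average_{g}.csv")

        stage = "detect+metrics"
        metric_rows = []
        partitions_by_t = {}
        for ti, t in enumerate(config.thresholds):
            parts = []
            for c, lab, sid in zip(conn, labels, subject_ids):
                net = binarize(c, t)
                part = detect_communities(net)
                parts.append(part)
                mv = compute_all(net, part, sid, t)
                metric_rows.append({
                    "subject_id": sid, "group": lab, "threshold": t,
                    **dict(zip(METRIC_NAMES, mv.as_tuple())),
                })
            partitions_by_t[t] = parts
            for g, avg in averages.items():
                net = binarize(avg, t)
                gp = detect_communities(net)
                write_partition_tsv(gp, out / f"partition_group_{g}_t{t:g}.tsv",
                                    avg.roi_labels)
        metrics = pd.DataFrame(metric_rows)
        metrics.to_csv(out / "metrics.csv", index=False, float_format="%.17g")

        stage = "group_stats"
        table = metric_group_table(metrics)
        table.to_csv(out / "group_comparison.csv", index=False, float_format="%.17g")
        kdes = kde_table(metrics)
        kdes.to_csv(out / "kde_curves.csv", index=False, float_format="%.17g")

        stage = "permutation_tests"
        perm_reports = {}
        nodal_results = {}
        for ti, t in enumerate(config.thresholds):
            parts = partitions_by_t[t]
            res = group_permutation_test(
                parts, labels, config.n_permutations_global,
                seed=_substream_seed(config.seed, 1, ti),
            )
            perm_reports[f"{t:g}"] = res.to_dict()
            if config.run_nodal:
                nres = nodal_permutation_test(
                    parts, labels, config.n_permutations_nodal,
                    seed=_substream_seed(config.seed, 2, ti),
                )
                nodal_results[t] = nres
                pd.DataFrame({
                    "node_label": conn[0].roi_labels,
                    "p": nres.per_node_p, "q": nres.per_node_q,
                }).to_csv(out / f"nodal_t{t:g}.csv", index=False, float_format="%.17g")
        _write_json(out / "permutation_global.json", perm_reports)

        stage = "classification"
        cls_reports = []
        rfe_reports = {}
        for ti, t in enumerate(config.thresholds):
            feats = FeatureTable.from_metrics(metrics, t)
            for clf in config.classifiers:
                for scheme in config.cv_schemes:
                    rep = cross_validate(
                        feats, clf, scheme,
                        seed=_substream_seed(config.seed, 3, ti),
                        k_neighbors=config.k_neighbors,
                    )
                    cls_reports.append(rep.to_dict())
            if config.run_rfe:
                rfe = rfe_rank(feats, "lda", seed=_substream_seed(config.seed, 4, ti))
                rfe_reports[f"{t:g}"] = rfe.to_dict()
        _write_json(out / "classification.json", cls_reports)
        if config.run_rfe:
            _write_json(out / "rfe.json", rfe_reports)

        stage = "run_log"
        log = {
            "commpat_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "thresholds": list(config.thresholds),
            "n_permutations_global": config.n_permutations_global,
            "n_permutations_nodal": config.n_permutations_nodal,
            "classifiers": list(config.classifiers),
            "cv_schemes": list(config.cv_schemes),
            "n_subjects": len(subject_ids),
            "groups": {g: int(sum(1 for x in labels if x == g)) for g in groups},
            "input_source": ("synthetic" if config.synthetic is not None
                             else "timeseries" if config.timeseries_manifest
                             else "connectivity"),
        }
        _write_json(out / "run_log.json", log)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return {
        "metrics": metrics,
        "group_table": table,
        "permutation_global": perm_reports,
        "nodal": nodal_results,
        "classification": cls_reports,
        "rfe": rfe_reports,
        "averages": averages,
        "partitions": partitions_by_t,
        "labels": labels,
    }


def _load_connectivity(config: RunConfig, out: Path):
    if config.synthetic is not None:
        cohort = generate_cohort(config.synthetic, out / "cohort")
    elif config.timeseries_manifest is not None:
        cohort = _read_ts_cohort(config.timeseries_manifest)
    else:
        mats = read_cohort(config.connectivity_manifest, kind="connectivity")
        return ([m for m, _ in mats], [g for _, g in mats],
                [m.subject_id for m, _ in mats])
    conn = [pearson_connectivity(s) for s in cohort.subjects]
    labels = [s.group for s in cohort.subjects]
    ids = [s.subject_id for s in cohort.subjects]
    return conn, labels, ids


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
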