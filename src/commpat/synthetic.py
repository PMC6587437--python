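"""Synthetic two-group ROI time-series cohorts with planted modular structure.

Each subject is a matrix of zero-mean, unit-variance Gaussian time courses
whose population correlation matrix is block-constant: ``rho_in`` within a
module, ``rho_out`` between modules.  Two group-difference mechanisms can be
planted: a signed shift ``delta_rho_in`` of the within-module correlation in
the case group (diffuse connectivity change), and reassignment of a chosen
set of "affected" nodes to the following module (focal community change).
Because every downstream stage consumes only Pearson correlations, which are
invariant to location and scale, this Gaussian model is the minimal generator
of the correlation structure the pipeline analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

GROUPS = ("control", "case")


class SpecValidationError(ValueError):
    """A SyntheticSpec invariant is violated; the message names it."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-group block-correlation cohort generator.

    Parameters
    ----------
    n_rois : number of network nodes (e.g. 90 for an AAL-style parcellation).
    n_timepoints : time points per subject (rows of the series matrix).
    block_sizes : module sizes; must sum to ``n_rois``.
    rho_in_control : within-module correlation of the control group, in [0, 1).
    rho_out : between-module correlation, in [0, rho_in_control).
    delta_rho_in : signed shift of the within-module correlation applied to
        the case group; ``rho_in_control + delta_rho_in`` must stay in [0, 1).
    affected_nodes : node indices whose module assignment is moved to the
        next module (cyclically) in the case group; may be empty.
    n_per_group : subjects per diagnostic group.
    seed : root seed; all randomness is derived from it.
    """

    n_rois: int = 90
    n_timepoints: int = 150
    block_sizes: tuple[int, ...] = (30, 30, 30)
    rho_in_control: float = 0.5
    rho_out: float = 0.1
    delta_rho_in: float = 0.0
    affected_nodes: frozenset[int] = frozenset()
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        object.__setattr__(self, "affected_nodes", frozenset(int(i) for i in self.affected_nodes))
        if any(b < 1 for b in self.block_sizes):
            raise SpecValidationError("every block size must be >= 1")
        if sum(self.block_sizes) != self.n_rois:
            raise SpecValidationError(
                f"sum(block_sizes)={sum(self.block_sizes)} != n_rois={self.n_rois}"
            )
        if not (0.0 <= self.rho_out <= self.rho_in_control < 1.0):
            raise SpecValidationError("require 0 <= rho_out <= rho_in_control < 1")
        if not (0.0 <= self.rho_in_control + self.delta_rho_in < 1.0):
            raise SpecValidationError("require 0 <= rho_in_control + delta_rho_in < 1")
        if self.affected_nodes and not all(0 <= i < self.n_rois for i in self.affected_nodes):
            raise SpecValidationError("affected_nodes must be a subset of {0..n_rois-1}")
        if self.n_timepoints < 3:
            raise SpecValidationError("n_timepoints must be >= 3")
        if self.n_per_group < 1:
            raise SpecValidationError("n_per_group must be >= 1")

    @property
    def roi_labels(self) -> list[str]:
        width = len(str(self.n_rois))
        return [f"ROI{i + 1:0{width}d}" for i in range(self.n_rois)]

    def block_assignment(self, group: str) -> np.ndarray:
        """Module index per node; case-group affected nodes move one module up."""
        _check_group(group)
        blocks = np.repeat(np.arange(len(self.block_sizes)), self.block_sizes)
        if group == "case" and self.affected_nodes:
            idx = np.array(sorted(self.affected_nodes))
            blocks = blocks.copy()
            blocks[idx] = (blocks[idx] + 1) % len(self.block_sizes)
        return blocks

    def rho_in(self, group: str) -> float:
        _check_group(group)
        return self.rho_in_control + (self.delta_rho_in if group == "case" else 0.0)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "block_sizes" in d:
            d["block_sizes"] = tuple(d["block_sizes"])
        if "affected_nodes" in d:
            d["affected_nodes"] = frozenset(d["affected_nodes"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SubjectTimeSeries:
    """One subject's ROI time courses (n_timepoints x n_rois)."""

    subject_id: str
    group: str
    series: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a 2-D matrix (timepoints x ROIs)")
        if self.series.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if np.isnan(self.series).any():
            raise ValueError("series contains missing values")
        if len(self.roi_labels) != self.series.shape[1]:
            raise ValueError("roi_labels length must equal the number of ROIs")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        _check_group(self.group)


@dataclass
class Cohort:
    subjects: list[SubjectTimeSeries]
    manifest: pd.DataFrame = field(default_factory=lambda: pd.DataFrame())

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")

    def group_members(self, group: str) -> list[SubjectTimeSeries]:
        _check_group(group)
        return [s for s in self.subjects if s.group == group]

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")


def build_block_covariance(spec: SyntheticSpec, group: str) -> np.ndarray:
    """Population covariance (= correlation) matrix for one group.

    Unit diagonal, ``rho_in(group)`` for same-module pairs (module membership
    after applying the case-group node reassignment), ``rho_out`` otherwise.
    If the block-constant matrix is not positive semidefinite it is shrunk
    toward the identity by the minimal factor restoring eigenvalue >= 1e-8,
    and the repair is logged.
    """
    blocks = spec.block_assignment(group)
    same = blocks[:, None] == blocks[None, :]
    cov = np.where(same, spec.rho_in(group), spec.rho_out)
    np.fill_diagonal(cov, 1.0)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min < 1e-8:
        # shrink (1-a)*C + a*I; smallest eigenvalue becomes (1-a)*lam_min + a
        target = 1e-8
        a = (target - lam_min) / (1.0 - lam_min)
        cov = (1.0 - a) * cov + a * np.eye(spec.n_rois)
        logger.warning(
            "covariance for group=%s not PSD (lambda_min=%.3e); shrunk toward identity by a=%.3e",
            group, lam_min, a,
        )
    return cov


def subject_rng(spec: SyntheticSpec, group: str, index: int) -> np.random.Generator:
    """Independent, reproducible substream keyed by (seed, group, index)."""
    _check_group(group)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(GROUPS.index(group), index))
    )


def sample_subject(
    spec: SyntheticSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str | None = None,
    cov: np.ndarray | None = None,
) -> SubjectTimeSeries:
    """Draw one subject: rows are i.i.d. N(0, cov) vectors."""
    if cov is None:
        cov = build_block_covariance(spec, group)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min < -1e-10:
        raise ValueError(f"covariance not PSD after repair (lambda_min={lam_min:.3e})")
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    z = rng.standard_normal((spec.n_timepoints, spec.n_rois))
    series = z @ chol.T
    if subject_id is None:
        subject_id = f"{group}_{id(rng):x}"
    return SubjectTimeSeries(subject_id, group, series, spec.roi_labels)


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate ``n_per_group`` subjects per group, optionally writing files.

    Subjects draw from per-subject substreams keyed by (seed, group, index),
    so the cohort is reproducible independently of generation order.  When
    ``out_dir`` is given, per-subject TSV files and a ``manifest.csv`` are
    written there.
    """
    subjects: list[SubjectTimeSeries] = []
    rows = []
    covs = {g: build_block_covariance(spec, g) for g in GROUPS}
    for group in GROUPS:
        for i in range(spec.n_per_group):
            sid = f"{group}{i + 1:03d}"
            ts = sample_subject(spec, group, subject_rng(spec, group, i), sid, covs[group])
            subjects.append(ts)
            rows.append({"subject_id": sid, "group": group, "path": f"{sid}.tsv"})
    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "path"])
    cohort = Cohort(subjects, manifest)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject TSVs (header = ROI labels) and the manifest CSV."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        for s in cohort.subjects:
            df = pd.DataFrame(s.series, columns=s.roi_labels)
            df.to_csv(out / f"{s.subject_id}.tsv", sep="\t", index=False, float_format="%.17g")
        cohort.manifest.to_csv(out / "manifest.csv", index=False)
    except OSError as exc:
        raise OSError(f"failed writing cohort under {out}: {exc}") from exc
    return out / "manifest.csv"


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a manifest CSV and the subject TSVs it points to."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"{manifest_path}: manifest must have columns {sorted(required)}")
    subjects = []
    n_rois = None
    for row in manifest.itertuples(index=False):
        path = manifest_path.parent / row.path
        try:
            df = pd.read_csv(path, sep="\t")
        except FileNotFoundError:
            raise FileNotFoundError(f"{manifest_path}: subject file missing: {path}")
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValueError(f"{path}: non-numeric values in column(s) {bad}")
        if n_rois is None:
            n_rois = df.shape[1]
        elif df.shape[1] != n_rois:
            raise ValueError(
                f"{path}: inconsistent ROI count {df.shape[1]} (expected {n_rois})"
            )
        subjects.append(
            SubjectTimeSeries(str(row.subject_id), str(row.group), df.to_numpy(), list(df.columns))
        )
    return Cohort(subjects, manifest)
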