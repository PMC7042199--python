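"""Synthetic two-group cohort generation.

A cohort is generated from a latent-factor model: every module (subnetwork)
has a shared latent signal, hub nodes additionally load on the other modules'
latents, and a set of "affected" node pairs share an extra pairwise latent
whose coupling is attenuated in the patient-like group.  The model only needs
to produce controllable pairwise Pearson correlations, which is all the
downstream network analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from connectoml.errors import ConfigurationError, NoGroundTruthError

PATIENT = "patient"
CONTROL = "control"
GROUPS = (PATIENT, CONTROL)


@dataclass(frozen=True)
class GroupCovariateParams:
    """Per-group covariate distribution: normal age/education, Bernoulli sex."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    male_proportion: float

    def validate(self, group: str) -> None:
        for name in ("age_sd", "education_sd"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(
                    f"covariate_params[{group!r}].{name} must be finite and > 0, got {value}"
                )
        for name in ("age_mean", "education_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(
                    f"covariate_params[{group!r}].{name} must be finite"
                )
        if not 0.0 <= self.male_proportion <= 1.0:
            raise ConfigurationError(
                f"covariate_params[{group!r}].male_proportion must be in [0, 1]"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the exported ground truth.

    ``module_assignment`` maps each ROI (0-based) to a 1-based contiguous
    module id.  ``affected_edges`` holds unordered ROI pairs whose latent
    coupling is multiplied by ``1 - edge_effect`` in the patient group.
    """

    n_patients: int
    n_controls: int
    n_rois: int
    n_timepoints: int
    module_assignment: tuple[int, ...]
    hub_rois: frozenset[int] = frozenset()
    affected_edges: frozenset[tuple[int, int]] = frozenset()
    edge_effect: float = 0.5
    edge_coupling: float = 0.8
    hub_gain: float = 0.6
    noise_sd: float = 1.0
    covariate_params: dict[str, GroupCovariateParams] = field(default_factory=dict)
    scalar_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    @property
    def n_modules(self) -> int:
        return len(set(self.module_assignment))

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ConfigurationError("n_patients and n_controls must be >= 1")
        if self.n_rois < 4:
            raise ConfigurationError(f"n_rois must be >= 4, got {self.n_rois}")
        if self.n_timepoints < 20:
            raise ConfigurationError(
                f"n_timepoints must be >= 20, got {self.n_timepoints}"
            )
        if len(self.module_assignment) != self.n_rois:
            raise ConfigurationError(
                "module_assignment must cover every ROI exactly once: "
                f"got {len(self.module_assignment)} entries for {self.n_rois} ROIs"
            )
        mods = sorted(set(self.module_assignment))
        if mods != list(range(1, len(mods) + 1)):
            raise ConfigurationError(
                "module ids must be contiguous starting at 1, got " f"{mods}"
            )
        for roi in self.hub_rois:
            if not 0 <= roi < self.n_rois:
                raise ConfigurationError(f"hub ROI {roi} outside [0, {self.n_rois})")
        for pair in self.affected_edges:
            i, j = pair
            if not (0 <= i < j < self.n_rois):
                raise ConfigurationError(
                    f"affected edge {pair} is not an unordered ROI pair with i < j"
                )
        if not 0.0 <= self.edge_effect <= 1.0:
            raise ConfigurationError(
                f"edge_effect must be in [0, 1], got {self.edge_effect}"
            )
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ConfigurationError(f"noise_sd must be finite and >= 0")
        for group, params in self.covariate_params.items():
            if group not in GROUPS:
                raise ConfigurationError(f"unknown covariate group {group!r}")
            params.validate(group)
        for name, per_group in self.scalar_params.items():
            for group, (_, sd) in per_group.items():
                if sd <= 0 or not np.isfinite(sd):
                    raise ConfigurationError(
                        f"scalar_params[{name!r}][{group!r}] SD must be finite and > 0"
                    )


@dataclass
class TimeSeriesCohort:
    """Per-subject ROI x time matrices with labels, covariates and truth."""

    subject_ids: list[str]
    data: list[np.ndarray]
    labels: np.ndarray  # of str in {"patient", "control"}
    covariates: pd.DataFrame  # subject_id, label, age, sex, education (+ scalars)
    truth: CohortSpec | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_rois(self) -> int:
        return self.data[0].shape[0]

    def y(self) -> np.ndarray:
        """Labels encoded as +1 (patient) / -1 (control)."""
        return np.where(self.labels == PATIENT, 1, -1)

    def validate(self) -> None:
        n = self.n_subjects
        if not (len(self.data) == len(self.labels) == len(self.covariates) == n):
            raise ConfigurationError("subjects, labels and covariates must align")
        n_rois = self.n_rois
        for sid, mat in zip(self.subject_ids, self.data):
            if mat.shape[0] != n_rois:
                raise ConfigurationError(
                    f"subject {sid}: expected {n_rois} ROIs, got {mat.shape[0]}"
                )
            if not np.all(np.isfinite(mat)):
                raise ConfigurationError(f"subject {sid}: non-finite values")


# Table-mirroring defaults: 39 patients / 60 controls, 264 ROIs split over 14
# modules, 230 retained time points.
_DEFAULT_COVARIATES = {
    PATIENT: GroupCovariateParams(74.00, 7.67, 10.97, 4.29, 25 / 39),
    CONTROL: GroupCovariateParams(71.25, 7.08, 12.42, 3.58, 30 / 60),
}
_DEFAULT_SCALARS = {
    "hippocampal_volume": {PATIENT: (6.80, 0.87), CONTROL: (7.43, 0.69)},
}


def _balanced_modules(n_rois: int, n_modules: int) -> tuple[int, ...]:
    return tuple(int(i * n_modules / n_rois) + 1 for i in range(n_rois))


def default_spec(
    n_patients: int = 39,
    n_controls: int = 60,
    n_rois: int = 264,
    n_timepoints: int = 230,
    n_modules: int = 14,
    edge_effect: float = 0.5,
    noise_sd: float = 1.0,
    n_affected_edges: int = 40,
    n_hubs: int = 8,
    seed: int = 0,
) -> CohortSpec:
    """Spec emulating the study design, scalable down for fast tests.

    Affected edges are planted between the first two modules (a "planted
    subnetwork"), hubs are spread evenly across ROIs.
    """
    assignment = _balanced_modules(n_rois, n_modules)
    module_arr = np.asarray(assignment)
    first = np.flatnonzero(module_arr == 1)
    second = np.flatnonzero(module_arr == 2)
    rng = np.random.default_rng(seed + 777)  # offset: structural draw only
    edges: set[tuple[int, int]] = set()
    while len(edges) < min(n_affected_edges, len(first) * len(second)):
        i = int(rng.choice(first))
        j = int(rng.choice(second))
        edges.add((min(i, j), max(i, j)))
    hubs = frozenset(int(r) for r in np.linspace(0, n_rois - 1, n_hubs).round())
    return CohortSpec(
        n_patients=n_patients,
        n_controls=n_controls,
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        module_assignment=assignment,
        hub_rois=hubs,
        affected_edges=frozenset(edges),
        edge_effect=edge_effect,
        noise_sd=noise_sd,
        covariate_params=dict(_DEFAULT_COVARIATES),
        scalar_params=dict(_DEFAULT_SCALARS),
        seed=seed,
    )


def generate_covariates(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject covariates from the per-group distributions.

    Returns a frame with columns subject_id, label, age, sex, education plus
    one column per scalar feature.  Deterministic given ``spec.seed`` when no
    generator is supplied.
    """
    spec.validate()
    if not spec.covariate_params:
        raise ConfigurationError("covariate_params is empty")
    for group in GROUPS:
        if group not in spec.covariate_params:
            raise ConfigurationError(f"covariate_params missing group {group!r}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rows = []
    counts = {PATIENT: spec.n_patients, CONTROL: spec.n_controls}
    for group in GROUPS:
        params = spec.covariate_params[group]
        n = counts[group]
        age = rng.normal(params.age_mean, params.age_sd, size=n)
        edu = rng.normal(params.education_mean, params.education_sd, size=n)
        male = rng.random(size=n) < params.male_proportion
        scalars = {
            name: rng.normal(*per_group[group], size=n)
            for name, per_group in spec.scalar_params.items()
            if group in per_group
        }
        for k in range(n):
            row = {
                "subject_id": f"{group[:3]}_{k:04d}",
                "label": group,
                "age": age[k],
                "sex": "M" if male[k] else "F",
                "education": edu[k],
            }
            for name, vals in scalars.items():
                row[name] = vals[k]
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> TimeSeriesCohort:
    """Simulate a cohort from the latent-factor model.

    Per subject: each module has an i.i.d. standard-normal latent series; a
    node's series is its module latent, plus (for hubs) a cross-module mixture,
    plus, for each affected pair, a shared pairwise latent scaled so that the
    pair covariance is multiplied by ``1 - edge_effect`` in patients, plus
    independent Gaussian noise.  All randomness flows from a single stream
    seeded with ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    covariates = generate_covariates(spec, rng=rng)

    module = np.asarray(spec.module_assignment) - 1  # 0-based
    n_mod = spec.n_modules
    T = spec.n_timepoints
    hubs = np.array(sorted(spec.hub_rois), dtype=int)
    edges = sorted(spec.affected_edges)

    data: list[np.ndarray] = []
    for label in covariates["label"]:
        latents = rng.standard_normal((n_mod, T))
        x = latents[module].copy()
        if hubs.size and n_mod > 1:
            # hubs mix in the other modules' latents, unit-variance scaled
            total = latents.sum(axis=0)
            for roi in hubs:
                other = (total - latents[module[roi]]) / np.sqrt(n_mod - 1)
                x[roi] += spec.hub_gain * other
        if edges:
            shared = rng.standard_normal((len(edges), T))
            w = spec.edge_coupling
            if label == PATIENT:
                w = w * np.sqrt(1.0 - spec.edge_effect)
            for e, (i, j) in enumerate(edges):
                x[i] += w * shared[e]
                x[j] += w * shared[e]
        x += spec.noise_sd * rng.standard_normal((spec.n_rois, T))
        data.append(x)

    cohort = TimeSeriesCohort(
        subject_ids=list(covariates["subject_id"]),
        data=data,
        labels=covariates["label"].to_numpy(),
        covariates=covariates,
        truth=spec,
    )
    cohort.validate()
    return cohort


def export_truth(cohort: TimeSeriesCohort) -> dict[str, pd.DataFrame]:
    """Ground-truth tables (affected edges, hub ROIs, module map) as frames.

    Raises :class:`NoGroundTruthError` for user-supplied cohorts.
    """
    if cohort.truth is None:
        raise NoGroundTruthError("cohort has no generating spec (user-supplied data)")
    spec = cohort.truth
    edges = pd.DataFrame(
        sorted(spec.affected_edges), columns=["roi_i", "roi_j"], dtype=int
    )
    hubs = pd.DataFrame({"roi_id": sorted(spec.hub_rois)}, dtype=int)
    modules = pd.DataFrame(
        {
            "roi_id": np.arange(spec.n_rois, dtype=int),
            "module_id": np.asarray(spec.module_assignment, dtype=int),
        }
    )
    return {"affected_edges": edges, "hub_rois": hubs, "modules": modules}


def scaled_spec(seed: int = 0, strong: bool = True) -> CohortSpec:
    """Scaled-down demo spec: 60 ROIs, 30+30 subjects, 6 modules."""
    spec = default_spec(
        n_patients=30,
        n_controls=30,
        n_rois=60,
        n_timepoints=120,
        n_modules=6,
        edge_effect=0.8 if strong else 0.0,
        noise_sd=0.8,
        n_affected_edges=25,
        n_hubs=4,
        seed=seed,
    )
    return spec
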