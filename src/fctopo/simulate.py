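"""Multi-site case-control cohort simulator for functional-connectome studies.

Emulates the statistical structure of a multi-site resting-state fMRI
case-control sample: several acquisition sites, patients (with
first-episode drug-naive / recurrent subtypes) and controls, node-level
BOLD-like time series drawn from a modular Gaussian covariance template,
multiplicative site- and group-level perturbations of connectivity, and
realistic demographic/clinical covariates.

The generative model for a subject's node covariance is

    Sigma_subj = scale * (Sigma_template - I) + I,
    scale = delta_subject * exp(b_site + s_site * patient + sum_c beta_c x_c)

where ``delta_subject`` is a multiplicative attenuation of connectivity
in patients (1 = null), ``b_site``/``s_site`` are per-site random
intercepts/slopes on the log-connectivity scale, and the ``beta_c`` are
optional covariate effects. Time samples are i.i.d. multivariate normal:
temporal autocorrelation is deliberately not modeled, since the
downstream pipeline consumes only static Pearson correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .nodes import NETWORK_LABELS, NodeSet

__all__ = [
    "SyntheticSpec",
    "SubjectRecord",
    "Cohort",
    "build_covariance_template",
    "module_assignments",
    "synthetic_node_set",
    "synthesize_subject",
    "synthesize_cohort",
    "synthesize_outcome",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-site cohort.

    Defaults emulate a 16-site consortium sample (~50 subjects per group
    per site, 160 nodes) with a 7-module covariance template. Noise and
    site-effect scales are stated once here and documented in the
    methods note; acceptance simulations override the size parameters
    explicitly.
    """

    n_sites: int = 16
    n_per_group_per_site: int | list[int] = 50
    n_nodes: int = 160
    n_timepoints: int = 200
    n_modules: int = 7
    within_module_r: float = 0.4
    between_module_r: float = 0.05
    #: multiplicative attenuation of patient connectivity (1 = null)
    group_effect_delta: float = 1.0
    #: optional per-subtype override of group_effect_delta
    subtype_deltas: dict[str, float] | None = None
    site_intercept_sd: float = 0.1
    site_slope_sd: float = 0.05
    covariate_effects: dict[str, float] = field(default_factory=dict)
    #: fractions of FEDN / recurrent among patients; remainder -> unknown
    subtype_fractions: dict[str, float] = field(
        default_factory=lambda: {"FEDN": 0.42, "recurrent": 0.32}
    )
    #: HAMD ~ hamd_base + hamd_slope * (1 - scale) + N(0, hamd_noise_sd)
    hamd_base: float = 21.0
    hamd_slope: float = 0.0
    hamd_noise_sd: float = 4.0
    #: probability a patient is on antidepressant medication
    medicated_fraction: float = 0.42
    #: residual sd of the direct AUC-level outcome generator
    outcome_noise_sd: float = 1.0
    #: also draw a per-timepoint framewise-displacement series (for scrubbing)
    generate_fd_series: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        sizes = self.group_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("need at least one subject per group per site")
        if not (0 <= self.between_module_r < self.within_module_r < 1):
            raise ValueError(
                "require 0 <= between_module_r < within_module_r < 1"
            )
        if not 0 <= self.group_effect_delta <= 1:
            raise ValueError("group_effect_delta must lie in [0, 1]")
        fr = sum(self.subtype_fractions.values())
        if fr > 1 + 1e-12 or any(v < 0 for v in self.subtype_fractions.values()):
            raise ValueError("subtype_fractions must be non-negative, sum <= 1")
        bad = set(self.subtype_fractions) - {"FEDN", "recurrent", "unknown"}
        if bad:
            raise ValueError(f"unknown subtype keys: {sorted(bad)}")

    def group_sizes(self) -> list[int]:
        """Per-site per-group sample size, expanded to one entry per site."""
        if isinstance(self.n_per_group_per_site, int):
            return [self.n_per_group_per_site] * self.n_sites
        sizes = list(self.n_per_group_per_site)
        if len(sizes) != self.n_sites:
            raise ValueError("n_per_group_per_site list must have n_sites entries")
        return sizes

    def delta_for(self, subtype: str) -> float:
        if self.subtype_deltas and subtype in self.subtype_deltas:
            return self.subtype_deltas[subtype]
        return self.group_effect_delta


@dataclass
class SubjectRecord:
    """One simulated (or loaded) subject: covariates plus node time series."""

    subject_id: str
    site_id: str
    group: str  # "NC" or "MDD"
    subtype: str  # "FEDN" | "recurrent" | "unknown" | "none"
    age: float
    sex: str  # "male" | "female"
    education: float
    mean_fd: float
    hamd: float | None = None
    on_medication: bool | None = None
    timeseries: np.ndarray | None = None  # nodes x time
    fd_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group not in ("NC", "MDD"):
            raise ValueError(f"invalid group {self.group!r}")
        if self.group == "MDD":
            if self.subtype not in ("FEDN", "recurrent", "unknown"):
                raise ValueError("patient subtype must be FEDN/recurrent/unknown")
        elif self.subtype != "none":
            raise ValueError("controls must have subtype 'none'")
        if self.hamd is not None and self.group != "MDD":
            raise ValueError("HAMD defined only for patients")
        if self.timeseries is not None:
            self.timeseries = np.asarray(self.timeseries, dtype=float)
            if self.timeseries.ndim != 2 or self.timeseries.shape[1] < 2:
                raise ValueError("timeseries must be nodes x time with >= 2 samples")
            if not np.all(np.isfinite(self.timeseries)):
                raise ValueError("timeseries contains non-finite values")
        for name in ("age", "education", "mean_fd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite covariate {name}")


@dataclass
class Cohort:
    """A list of subjects plus the node set their matrices are bound to."""

    subjects: list[SubjectRecord]
    node_set: NodeSet

    def __len__(self) -> int:
        return len(self.subjects)

    def covariates_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "site_id": s.site_id,
                    "group": s.group,
                    "subtype": s.subtype,
                    "age": s.age,
                    "sex": s.sex,
                    "education": s.education,
                    "mean_fd": s.mean_fd,
                    "hamd": s.hamd,
                    "on_medication": s.on_medication,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        """Serialize to covariates.csv + nodes.csv + one TSV per subject."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates_frame().to_csv(out / "covariates.csv", index=False)
        self.node_set.to_csv(out / "nodes.csv")
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for s in self.subjects:
            if s.timeseries is not None:
                np.savetxt(ts_dir / f"{s.subject_id}.tsv", s.timeseries,
                           delimiter="\t", fmt="%.10g")
        if any(s.fd_series is not None for s in self.subjects):
            fd_dir = out / "fd"
            fd_dir.mkdir(exist_ok=True)
            for s in self.subjects:
                if s.fd_series is not None:
                    np.savetxt(fd_dir / f"{s.subject_id}.tsv", s.fd_series,
                               fmt="%.10g")

    @classmethod
    def read(cls, in_dir) -> "Cohort":
        src = Path(in_dir)
        cov = pd.read_csv(src / "covariates.csv")
        node_set = NodeSet.from_csv(src / "nodes.csv")
        subjects = []
        for _, r in cov.iterrows():
            ts_path = src / "timeseries" / f"{r.subject_id}.tsv"
            ts = np.loadtxt(ts_path, delimiter="\t") if ts_path.exists() else None
            fd_path = src / "fd" / f"{r.subject_id}.tsv"
            fd = np.loadtxt(fd_path) if fd_path.exists() else None
            hamd = None if pd.isna(r.hamd) else float(r.hamd)
            med = None if pd.isna(r.on_medication) else bool(r.on_medication)
            subjects.append(
                SubjectRecord(
                    subject_id=str(r.subject_id), site_id=str(r.site_id),
                    group=str(r.group), subtype=str(r.subtype),
                    age=float(r.age), sex=str(r.sex),
                    education=float(r.education), mean_fd=float(r.mean_fd),
                    hamd=hamd, on_medication=med, timeseries=ts, fd_series=fd,
                )
            )
        return cls(subjects=subjects, node_set=node_set)


def module_assignments(n_nodes: int, n_modules: int) -> np.ndarray:
    """Assign nodes to modules in contiguous equal blocks, remainder to last."""
    if not 1 <= n_modules <= n_nodes:
        raise ValueError("require 1 <= n_modules <= n_nodes")
    size = n_nodes // n_modules
    labels = np.repeat(np.arange(n_modules), size)
    return np.concatenate([labels, np.full(n_nodes - labels.size, n_modules - 1)])


def _repair_psd(mat: np.ndarray, tol: float = -1e-10) -> np.ndarray:
    """Clip negative eigenvalues to zero and renormalize to unit diagonal.

    Deterministic: eigendecomposition of a symmetric matrix followed by
    reconstruction. Raises if the repaired matrix still fails PSD.
    """
    sym = (mat + mat.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= tol:
        return sym
    repaired = (vecs * np.clip(vals, 0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    smallest = np.linalg.eigvalsh((repaired + repaired.T) / 2)[0]
    if smallest < tol:
        raise ValueError(
            f"covariance repair failed; smallest eigenvalue {smallest:.3e}"
        )
    return (repaired + repaired.T) / 2


def build_covariance_template(
    n_nodes: int,
    n_modules: int,
    within_module_r: float,
    between_module_r: float,
) -> np.ndarray:
    """Block-modular correlation template with unit diagonal.

    Entries are ``within_module_r`` inside a module, ``between_module_r``
    across modules. The result is repaired to the nearest unit-diagonal
    PSD matrix by eigenvalue clipping if numerically indefinite.
    """
    if not (0 <= between_module_r < within_module_r < 1) and not (
        within_module_r == between_module_r == 0
    ):
        raise ValueError("require 0 <= between_module_r < within_module_r < 1")
    mods = module_assignments(n_nodes, n_modules)
    same = mods[:, None] == mods[None, :]
    tpl = np.where(same, within_module_r, between_module_r)
    np.fill_diagonal(tpl, 1.0)
    return _repair_psd(tpl)


def synthetic_node_set(
    n_nodes: int, n_modules: int, rng: np.random.Generator
) -> NodeSet:
    """Synthetic node table: module-clustered coordinates, cycling labels.

    Coordinates are drawn in an MNI-sized box around per-module centers;
    module m gets the m-th (mod 7) functional network label, so that
    injected modular structure aligns with the label vocabulary.
    """
    mods = module_assignments(n_nodes, n_modules)
    centers = rng.uniform(-60, 60, size=(n_modules, 3))
    coords = centers[mods] + rng.normal(scale=8.0, size=(n_nodes, 3))
    labels = [NETWORK_LABELS[m % 7] for m in mods]
    ids = [f"n{i:04d}" for i in range(n_nodes)]
    return NodeSet(node_ids=ids, coordinates=coords, network_labels=labels)


def _scale_offdiag(template: np.ndarray, scale: float) -> np.ndarray:
    """Multiply off-diagonal entries by ``scale``, keep validity.

    For 0 <= scale <= 1 this is a convex combination of the template and
    the identity and therefore PSD by construction; larger scales are
    clipped to valid correlations and PSD-repaired.
    """
    sigma = scale * template
    np.fill_diagonal(sigma, 1.0)
    if 0 <= scale <= 1:
        return sigma
    off = ~np.eye(sigma.shape[0], dtype=bool)
    sigma[off] = np.clip(sigma[off], -0.999, 0.999)
    return _repair_psd(sigma)


def _draw_covariates(group: str, rng: np.random.Generator, spec: SyntheticSpec) -> dict:
    """Documented default covariate distributions (see methods note)."""
    return {
        "age": rng.uniform(18, 60),
        # female preponderance among patients mirrors typical MDD samples
        "sex": "female" if rng.random() < (0.64 if group == "MDD" else 0.5) else "male",
        "education": rng.uniform(6, 20),
        "mean_fd": abs(rng.normal(0.10, 0.05)),
    }


def synthesize_subject(
    template: np.ndarray,
    group: str,
    site_effects: tuple[float, float],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    subject_id: str = "sub",
    site_id: str = "site",
    subtype: str | None = None,
    covariates: dict | None = None,
) -> SubjectRecord:
    """Draw one subject's covariates and node-by-time series.

    ``site_effects`` is the (intercept, slope) pair of the subject's site
    on the log-connectivity scale; the slope applies to patients only.
    """
    if group not in ("NC", "MDD"):
        raise ValueError(f"invalid group label {group!r}")
    if subtype is None:
        subtype = "unknown" if group == "MDD" else "none"
    cov = covariates if covariates is not None else _draw_covariates(group, rng, spec)
    for k, v in cov.items():
        if k != "sex" and not np.isfinite(v):
            raise ValueError(f"non-finite covariate {k}")
    b_site, s_site = site_effects
    patient = 1.0 if group == "MDD" else 0.0
    delta = spec.delta_for(subtype) if group == "MDD" else 1.0
    log_scale = b_site + s_site * patient
    for name, beta in spec.covariate_effects.items():
        val = cov[name] if name != "sex" else (1.0 if cov["sex"] == "male" else 0.0)
        log_scale += beta * float(val)
    scale = delta * np.exp(log_scale)
    sigma = _scale_offdiag(template, scale)
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(sigma.shape[0]))
    ts = chol @ rng.standard_normal((sigma.shape[0], spec.n_timepoints))

    fd_series = None
    if spec.generate_fd_series:
        # spiky motion trace whose mean tracks the subject's mean_fd covariate
        fd_series = np.abs(rng.normal(cov["mean_fd"], 0.6 * cov["mean_fd"],
                                      spec.n_timepoints))

    hamd = None
    on_med = None
    if group == "MDD":
        raw = spec.hamd_base + spec.hamd_slope * (1 - scale) + rng.normal(
            0, spec.hamd_noise_sd
        )
        hamd = float(np.round(max(raw, 0.0)))
        on_med = bool(rng.random() < spec.medicated_fraction)

    return SubjectRecord(
        subject_id=subject_id, site_id=site_id, group=group, subtype=subtype,
        age=cov["age"], sex=cov["sex"], education=cov["education"],
        mean_fd=cov["mean_fd"], hamd=hamd, on_medication=on_med, timeseries=ts,
        fd_series=fd_series,
    )


def _draw_subtype(rng: np.random.Generator, spec: SyntheticSpec) -> str:
    fr = spec.subtype_fractions
    p_fedn = fr.get("FEDN", 0.0)
    p_rec = fr.get("recurrent", 0.0)
    u = rng.random()
    if u < p_fedn:
        return "FEDN"
    if u < p_fedn + p_rec:
        return "recurrent"
    return "unknown"


def synthesize_cohort(spec: SyntheticSpec) -> Cohort:
    """Generate the full multi-site cohort described by ``spec``.

    Site random effects are drawn once per site; subjects then draw
    covariates, subtype and time series sequentially from a single
    stream, so identical specs (including seed) give bit-identical
    cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    template = build_covariance_template(
        spec.n_nodes, spec.n_modules, spec.within_module_r, spec.between_module_r
    )
    node_set = synthetic_node_set(spec.n_nodes, spec.n_modules, rng)
    site_int = rng.normal(0, spec.site_intercept_sd, size=spec.n_sites)
    site_slope = rng.normal(0, spec.site_slope_sd, size=spec.n_sites)
    subjects: list[SubjectRecord] = []
    sizes = spec.group_sizes()
    for si in range(spec.n_sites):
        site_id = f"site{si:02d}"
        for group in ("NC", "MDD"):
            for k in range(sizes[si]):
                subtype = _draw_subtype(rng, spec) if group == "MDD" else "none"
                sid = f"{site_id}_{group}_{k:03d}"
                subjects.append(
                    synthesize_subject(
                        template, group, (site_int[si], site_slope[si]),
                        spec, rng, subject_id=sid, site_id=site_id,
                        subtype=subtype,
                    )
                )
    return Cohort(subjects=subjects, node_set=node_set)


def synthesize_outcome(
    covariates: pd.DataFrame,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a subject-level outcome directly at the AUC level.

    Shortcut generator matching the mixed-model structure the inference
    stage assumes: per-site random intercepts and patient slopes, a group
    shift of ``log(delta)`` (0 under the null), optional covariate
    slopes, and i.i.d. Gaussian residuals. Used for fast calibration
    studies where simulating time series would only add cost.
    """
    sites = covariates["site_id"].to_numpy()
    uniq = list(dict.fromkeys(sites))
    b = dict(zip(uniq, rng.normal(0, spec.site_intercept_sd, len(uniq))))
    s = dict(zip(uniq, rng.normal(0, spec.site_slope_sd, len(uniq))))
    y = np.empty(len(covariates))
    for i, (_, r) in enumerate(covariates.iterrows()):
        patient = 1.0 if r.group == "MDD" else 0.0
        delta = spec.delta_for(str(r.subtype)) if patient else 1.0
        mu = b[r.site_id] + (s[r.site_id] + np.log(delta)) * patient
        for name, beta in spec.covariate_effects.items():
            val = r[name] if name != "sex" else (1.0 if r.sex == "male" else 0.0)
            mu += beta * float(val)
        y[i] = mu
    return y + rng.normal(0, spec.outcome_noise_sd, len(y))


# re-export for convenience in pipeline configs
def null_spec(**overrides) -> SyntheticSpec:
    """A null-world spec: no group effect, no site-by-group slope."""
    base = SyntheticSpec(group_effect_delta=1.0, site_slope_sd=0.0)
    return replace(base, **overrides)
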