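"""Synthetic inputs: tensor-field phantoms, toy parcellations, subject cohorts.

The cohort generator encodes the group pattern the pipeline is designed to
detect: a patient group whose networks contain fewer and weaker *low-weight*
edges than controls, on a shared small-world backbone, with lognormal
per-subject weight noise and standard nuisance covariates (age, sex, total
intracranial volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tracking import TensorField
from .netbuild import Connectome, Parcellation

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_parcellation",
    "template_network",
    "simulate_cohort",
]

GEOMETRIES = ("straight_bundle", "curved_bundle", "crossing", "isotropic")

#: mean diffusivity used for all generated tensors (mm^2/s, typical white matter)
MEAN_DIFFUSIVITY = 0.7e-3


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Recipe for a synthetic diffusion-tensor phantom.

    ``curvature_per_step`` is the in-plane direction change, in degrees, per
    ``step_ref_mm`` of travel along x (curved geometry only); with the default
    ``step_ref_mm`` equal to the standard 0.5 mm tracking step, it is the
    turning angle a tracker sees per step.
    """

    grid_shape: tuple[int, int, int] = (20, 10, 10)
    voxel_size: float = 1.0
    geometry: str = "straight_bundle"
    bundle_fa: float = 0.8
    background_fa: float = 0.0
    bundle_width: int = 2          # voxels across the bundle cross-section
    curvature_per_step: float = 0.0
    step_ref_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; expected one of {GEOMETRIES}")
        if not (0 <= self.bundle_fa <= 1 and 0 <= self.background_fa <= 1):
            raise ValueError("bundle_fa and background_fa must lie in [0, 1]")
        if any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape entries must all be >= 4")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.curvature_per_step < 0:
            raise ValueError("curvature_per_step must be >= 0")


def _radial_ratio(fa: float) -> float:
    """lambda_perp / lambda_parallel for an axially symmetric tensor with the
    requested FA.  FA = (1-r) / sqrt(1 + 2 r^2) for r in [0, 1]."""
    if fa <= 0:
        return 1.0
    if fa >= 1:
        return 0.0
    # (2 FA^2 - 1) r^2 + 2 r + (FA^2 - 1) = 0, take the root in [0, 1]
    a, b, c = 2 * fa * fa - 1, 2.0, fa * fa - 1
    if abs(a) < 1e-12:
        return -c / b
    disc = b * b - 4 * a * c
    r = (-b + np.sqrt(disc)) / (2 * a)
    if not 0 <= r <= 1:
        r = (-b - np.sqrt(disc)) / (2 * a)
    return float(r)


def _tensor_for(direction: np.ndarray, fa: float,
                md: float = MEAN_DIFFUSIVITY) -> np.ndarray:
    """Axially symmetric tensor with principal axis `direction`, given FA and
    mean diffusivity."""
    r = _radial_ratio(fa)
    lam1 = 3 * md / (1 + 2 * r)
    lam2 = r * lam1
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return lam2 * np.eye(3) + (lam1 - lam2) * np.outer(d, d)


def _bundle_slab(n: int, width: int) -> slice:
    lo = max(0, n // 2 - width // 2)
    return slice(lo, min(n, lo + width))


def make_phantom(spec: PhantomSpec) -> TensorField:
    """Build a tensor-field phantom for the requested geometry.

    Geometries
    ----------
    isotropic
        Every voxel has FA = ``background_fa`` (principal axis +z if > 0).
    straight_bundle
        A bundle along +x of square cross-section ``bundle_width`` voxels,
        FA = ``bundle_fa``; isotropic-like background at ``background_fa``.
    curved_bundle
        Whole volume filled with in-plane directions rotating with x:
        theta(x) = curvature_per_step * (x / step_ref_mm) degrees.
    crossing
        Two orthogonal straight bundles (along x and along y); in overlap
        voxels the two tensors are averaged, which lowers FA.
    """
    nx, ny, nz = spec.grid_shape
    tensors = np.empty((nx, ny, nz, 3, 3))
    bg = _tensor_for([0, 0, 1], spec.background_fa)
    tensors[...] = bg

    if spec.geometry == "isotropic":
        pass
    elif spec.geometry == "straight_bundle":
        sy = _bundle_slab(ny, spec.bundle_width)
        sz = _bundle_slab(nz, spec.bundle_width)
        tensors[:, sy, sz] = _tensor_for([1, 0, 0], spec.bundle_fa)
    elif spec.geometry == "crossing":
        sy = _bundle_slab(ny, spec.bundle_width)
        sz = _bundle_slab(nz, spec.bundle_width)
        sx = _bundle_slab(nx, spec.bundle_width)
        tx = _tensor_for([1, 0, 0], spec.bundle_fa)
        ty = _tensor_for([0, 1, 0], spec.bundle_fa)
        tensors[:, sy, sz] = tx
        tensors[sx, :, sz] = ty
        # overlap: compose the two populations by averaging their tensors
        tensors[sx, sy, sz] = 0.5 * (tx + ty)
    elif spec.geometry == "curved_bundle":
        rate = np.deg2rad(spec.curvature_per_step) / spec.step_ref_mm  # rad/mm
        xs = (np.arange(nx) * spec.voxel_size)
        for i, x in enumerate(xs):
            theta = rate * x
            d = np.array([np.cos(theta), np.sin(theta), 0.0])
            tensors[i, :, :] = _tensor_for(d, spec.bundle_fa)
    return TensorField(tensors, voxel_size=spec.voxel_size)


def bundle_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of bundle voxels (straight/crossing geometries)."""
    nx, ny, nz = spec.grid_shape
    m = np.zeros(spec.grid_shape, dtype=bool)
    if spec.geometry in ("straight_bundle", "crossing"):
        sy = _bundle_slab(ny, spec.bundle_width)
        sz = _bundle_slab(nz, spec.bundle_width)
        m[:, sy, sz] = True
        if spec.geometry == "crossing":
            sx = _bundle_slab(nx, spec.bundle_width)
            m[sx, :, sz] = True
    elif spec.geometry == "curved_bundle":
        m[...] = True
    return m


# ---------------------------------------------------------------------------
# Parcellations
# ---------------------------------------------------------------------------

def make_parcellation(grid_shape: tuple[int, int, int], n_regions: int,
                      seed: int = 0, voxel_size: float = 1.0,
                      scheme: str = "slab") -> Parcellation:
    """Partition a voxel grid into ``n_regions`` labelled regions.

    scheme="slab" chunks voxels in lexicographic order into equal-count
    contiguous slabs (fully deterministic); scheme="voronoi" draws random
    region centres and labels each voxel by its nearest centre (deterministic
    given ``seed``; every cell contains its own centre, so no label is empty).
    """
    n_vox = int(np.prod(grid_shape))
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if n_regions > n_vox:
        raise ValueError(f"n_regions={n_regions} exceeds {n_vox} voxels")
    labels = np.zeros(grid_shape, dtype=np.int32)
    coords = np.indices(grid_shape).reshape(3, -1).T  # lexicographic order
    if scheme == "slab":
        chunks = np.array_split(np.arange(n_vox), n_regions)
        flat = np.empty(n_vox, dtype=np.int32)
        for lab, chunk in enumerate(chunks, start=1):
            flat[chunk] = lab
        labels = flat.reshape(grid_shape)
    elif scheme == "voronoi":
        rng = np.random.default_rng(seed)
        centres = coords[rng.choice(n_vox, size=n_regions, replace=False)]
        d2 = ((coords[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        labels = (d2.argmin(axis=1) + 1).astype(np.int32).reshape(grid_shape)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    affine = np.diag([voxel_size] * 3 + [1.0])
    return Parcellation(labels=labels, affine=affine, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generative settings for a two-group synthetic connectome cohort.

    The template network is a Watts-Strogatz small-world backbone with
    distance-decaying lognormal weights.  Patients have each lowest-quartile
    ("weak") template edge deleted with probability ``weak_edge_deletion_prob``
    and their weights attenuated in a weight-rank-graded way: the weakest
    template edge is multiplied by ``weight_attenuation`` and the factor fades
    quadratically (in weight-quantile rank) to 1 at the strongest edge, so the
    weakening persists across most of the weight range.  Grading is
    what makes the effect visible to max-normalised weighted metrics — a
    uniform multiplicative factor would cancel exactly under division by the
    network maximum — and matches the observed pattern of weak edges being
    preferentially weakened.  Every subject's edge weights carry independent
    lognormal noise of sigma ``subject_noise_sd``.  ``covariate_effects`` maps
    covariate column names to linear slopes applied to log-weights of the
    standardized covariate.
    """

    n_controls: int = 25
    n_patients: int = 25
    n_nodes: int = 90
    base_density: float = 0.25
    rewire_prob: float = 0.1
    template_weight_sd: float = 0.5
    distance_decay: float = 0.05   # e-folding rate of weight vs ring distance
    weak_edge_deletion_prob: float = 0.0
    weight_attenuation: float = 1.0
    subject_noise_sd: float = 0.25
    covariate_effects: dict = field(default_factory=dict)
    missing_rate: float = 0.0      # missingness in cognitive/disease columns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("group sizes must be positive")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        if not 0 < self.base_density <= 1:
            raise ValueError("base_density must lie in (0, 1]")
        for name in ("weak_edge_deletion_prob", "rewire_prob", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.weight_attenuation <= 1:
            raise ValueError("weight_attenuation must lie in (0, 1]")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")


def template_network(spec: CohortSpec) -> np.ndarray:
    """Symmetric weighted template adjacency (n_nodes x n_nodes).

    Watts-Strogatz ring-lattice rewiring at ``rewire_prob`` sets the topology;
    weights are lognormal with a mean that decays with ring distance, giving
    the heavy-tailed, distance-penalised weight profile tractography produces.
    """
    import networkx as nx

    n = spec.n_nodes
    k = max(2, int(round(spec.base_density * (n - 1) / 2)) * 2)
    rng = np.random.default_rng(spec.seed)
    g = nx.watts_strogatz_graph(n, k, spec.rewire_prob,
                                seed=int(rng.integers(2 ** 31)))
    W = np.zeros((n, n))
    for i, j in g.edges():
        ring = min(abs(i - j), n - abs(i - j))
        w = np.exp(rng.normal(0.0, spec.template_weight_sd)
                   - spec.distance_decay * ring)
        W[i, j] = W[j, i] = w
    return W


def _weak_edge_list(W: np.ndarray) -> np.ndarray:
    """Index pairs (i<j) of the lowest-quartile nonzero template weights."""
    iu = np.triu_indices_from(W, k=1)
    w = W[iu]
    present = w > 0
    cut = np.quantile(w[present], 0.25)
    weak = present & (w <= cut)
    return np.column_stack([iu[0][weak], iu[1][weak]])


def _covariate_table(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_controls + spec.n_patients
    group = np.array(["control"] * spec.n_controls + ["patient"] * spec.n_patients)
    age = rng.uniform(51, 84, size=n)
    sex = np.tile([0, 1], n // 2 + 1)[:n]  # balanced
    tiv = rng.normal(1430e3, 90e3, size=n)  # mm^3
    iq = rng.normal(107, 12, size=n)
    df = pd.DataFrame({
        "id": [f"sub-{i:03d}" for i in range(n)],
        "group": group,
        "age": age,
        "sex": sex,
        "TIV": tiv,
        "premorbid_IQ": iq,
    })
    # cognitive scores: all subjects; plausible scales, no built-in network link
    df["executive"] = rng.normal(11, 2.6, size=n)
    df["episodic_memory"] = rng.normal(10, 2.8, size=n)
    df["processing_speed"] = rng.normal(99, 21, size=n)
    df["working_memory"] = rng.normal(100, 15, size=n)
    df["MMSE"] = np.clip(np.rint(rng.normal(29, 1.5, size=n)), 0, 30)
    # disease measures: patients only (controls NaN, as in a clinical cohort)
    pat = df["group"].to_numpy() == "patient"
    for col, mu, sd in [("FSRP", 7.2, 4.1), ("pack_years", 53.5, 20.0),
                        ("exacerbations", 1.5, 1.5), ("FEV1pct", 52.5, 21.1),
                        ("FVCpct", 86.0, 32.1), ("PO2", 9.9, 1.8),
                        ("PCO2", 5.0, 0.7), ("SGRQ", 53.7, 30.0)]:
        v = np.full(n, np.nan)
        v[pat] = rng.normal(mu, sd, size=pat.sum())
        df[col] = v
    if spec.missing_rate > 0:
        cog = ["executive", "episodic_memory", "processing_speed",
               "working_memory", "MMSE"]
        for col in cog:
            miss = rng.random(n) < spec.missing_rate
            df.loc[miss, col] = np.nan
    return df


def simulate_cohort(spec: CohortSpec) -> tuple[list[Connectome], pd.DataFrame]:
    """Generate per-subject connectomes and the cohort covariate table.

    Every subject starts from the common template; patients have weak-quartile
    edges deleted and weights attenuated (rank-graded, strongest toward
    weakest); lognormal noise and optional linear covariate effects (on
    log-weights) are applied per subject.  Bit-identical outputs for identical
    specs and seeds.
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(spec.seed)
    template = template_network(spec)
    weak = _weak_edge_list(template)
    table = _covariate_table(spec, rng)
    n = spec.n_nodes
    iu = np.triu_indices(n, k=1)
    # per-edge attenuation factor for patients: weight_attenuation at the
    # weakest present edge, 1 at the strongest (quantile-rank graded)
    tw = template[iu]
    present = tw > 0
    atten = np.ones_like(tw)
    if spec.weight_attenuation < 1 and present.any():
        q = np.zeros_like(tw)
        q[present] = (rankdata(tw[present]) - 1) / max(present.sum() - 1, 1)
        atten[present] = spec.weight_attenuation + \
            (1.0 - spec.weight_attenuation) * q[present] ** 2
    zcov = {}
    for name in spec.covariate_effects:
        col = table[name].to_numpy(dtype=float)
        zcov[name] = (col - col.mean()) / (col.std() or 1.0)

    connectomes: list[Connectome] = []
    for s in range(len(table)):
        w = template[iu].copy()
        is_patient = table["group"].iloc[s] == "patient"
        if is_patient:
            if spec.weak_edge_deletion_prob > 0 and len(weak):
                drop = rng.random(len(weak)) < spec.weak_edge_deletion_prob
                for i, j in weak[drop]:
                    pos = np.searchsorted(iu[0] * n + iu[1], i * n + j)
                    w[pos] = 0.0
            w *= atten
        if spec.subject_noise_sd > 0:
            noise = rng.normal(0.0, spec.subject_noise_sd, size=w.shape)
            w = np.where(w > 0, w * np.exp(noise), 0.0)
        scale = 1.0
        for name, slope in spec.covariate_effects.items():
            scale *= np.exp(slope * zcov[name][s])
        w *= scale
        W = np.zeros((n, n))
        W[iu] = w
        W += W.T
        connectomes.append(Connectome.from_weights(
            W, strategy="synthetic", subject_id=table["id"].iloc[s]))
    return connectomes, table
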