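"""Synthetic two-group regional datasets with controllable covariance topology.

The generator draws subjects from a multivariate normal whose correlation
matrix realizes a chosen inter-regional topology:

* ``modular`` — equal-sized blocks with a common within-module correlation
  and a weaker between-module level (the default mimics the modular
  organization typical of structural covariance networks: 5 modules,
  within r = 0.5, between r = 0.1);
* ``lattice`` — correlation decaying exponentially with index distance on a
  ring, giving locally clustered, lattice-like networks;
* ``random`` — weak unstructured correlations from a random-factor model;
* ``custom`` — any user-supplied correlation matrix.

A group effect attenuates the within-module correlations of group B by a
multiplicative factor, emulating a diffuse loss of coordinated structure.
Optional i.i.d. measurement noise further attenuates all correlations.
Everything is reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi_extract import RegionalDataTable

__all__ = [
    "SyntheticSpec",
    "population_correlation",
    "generate_structural",
    "generate_functional",
    "write_nifti_fixture",
]


@dataclass
class SyntheticSpec:
    """Study-condition description for the synthetic generator."""

    n_regions: int = 20
    n_subjects_a: int = 20
    n_subjects_b: int = 20
    topology: str = "modular"          # modular | lattice | random | custom
    n_modules: int = 5
    within_r: float = 0.5
    between_r: float = 0.1
    custom_matrix: np.ndarray | None = None
    attenuation_b: float = 1.0         # multiplies group B within-module r
    noise_sd: float = 0.0              # i.i.d. measurement noise, data units
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        if self.n_subjects_a < 2 or self.n_subjects_b < 2:
            raise ValueError("need at least 2 subjects per group")
        for name, r in (("within_r", self.within_r),
                        ("between_r", self.between_r)):
            if not (-1 < r < 1):
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.topology not in ("modular", "lattice", "random", "custom"):
            raise ValueError(f"unknown topology: {self.topology!r}")
        if self.topology == "custom" and self.custom_matrix is None:
            raise ValueError("custom topology requires custom_matrix")


def _check_psd(C: np.ndarray, context: str) -> np.ndarray:
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8:
        nearest = (V * np.clip(w, 0, None)) @ V.T
        d = np.sqrt(np.diag(nearest))
        nearest = nearest / np.outer(d, d)
        raise ValueError(
            f"{context}: implied correlation matrix is not positive "
            "semi-definite (min eigenvalue "
            f"{w.min():.3g}); nearest PSD correlation matrix differs by "
            f"{np.abs(nearest - C).max():.3g} at most per entry — consider "
            "weaker correlation levels"
        )
    return C


def population_correlation(spec: SyntheticSpec, group: str = "a") -> np.ndarray:
    """The spec's population correlation matrix for one group."""
    n = spec.n_regions
    within = spec.within_r * (spec.attenuation_b if group == "b" else 1.0)
    if spec.topology == "modular":
        membership = np.arange(n) * spec.n_modules // n
        same = membership[:, None] == membership[None, :]
        C = np.where(same, within, spec.between_r).astype(float)
    elif spec.topology == "lattice":
        # geometric decay with ring distance: neighbours correlate at
        # within_r, second neighbours at within_r^2, ...; strictly PD
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        dist = np.minimum(dist, n - dist)
        C = np.abs(within) ** dist.astype(float)
        if within < 0:
            raise ValueError("lattice topology needs a nonnegative within_r")
    elif spec.topology == "random":
        rng = np.random.default_rng(
            spec.seed if spec.seed is not None else 0
        )
        F = rng.normal(size=(n, max(n // 2, 2)))
        C = F @ F.T
        d = np.sqrt(np.diag(C))
        C = 0.25 * C / np.outer(d, d)  # weak unstructured correlations
    else:
        C = np.asarray(spec.custom_matrix, dtype=float).copy()
        if group == "b":
            off = ~np.eye(n, dtype=bool)
            C[off] = C[off] * spec.attenuation_b
    np.fill_diagonal(C, 1.0)
    return _check_psd(C, f"topology {spec.topology!r}")


def _region_labels(n: int) -> list[str]:
    return [f"roi-{i:03d}" for i in range(n)]


def generate_structural(
    spec: SyntheticSpec,
) -> tuple[RegionalDataTable, RegionalDataTable]:
    """Two groups of regional data drawn from the spec's covariance models.

    Group A uses the nominal correlation structure; group B applies the
    within-module attenuation.  Measurement noise of SD ``noise_sd`` (the
    signal SD is 1) is added independently per entry.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _region_labels(spec.n_regions)
    tables = []
    for group, n_subj in (("a", spec.n_subjects_a), ("b", spec.n_subjects_b)):
        C = population_correlation(spec, group)
        X = rng.multivariate_normal(
            np.zeros(spec.n_regions), C, size=n_subj, method="eigh"
        )
        if spec.noise_sd > 0:
            X = X + rng.normal(0, spec.noise_sd, size=X.shape)
        tables.append(
            RegionalDataTable(
                X, labels,
                [f"{group}{i:03d}" for i in range(n_subj)],
                group=group.upper(),
            )
        )
    return tables[0], tables[1]


def generate_functional(
    spec: SyntheticSpec,
    n_subjects: int | None = None,
    as_zscores: bool = False,
) -> np.ndarray:
    """Per-subject association matrices around the population matrix.

    Returns a subjects x N x N array: population correlation plus symmetric
    subject-level noise of SD ``noise_sd``, clipped to [-1, 1], unit diagonal
    before zeroing.  With ``as_zscores`` the matrices are Fisher
    z-transformed (diagonal left at 0), matching toolchains that hand over
    z-scored connectivity.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    m = n_subjects if n_subjects is not None else spec.n_subjects_a
    C = population_correlation(spec, "a")
    out = np.empty((m, n, n))
    for s in range(m):
        E = rng.normal(0, spec.noise_sd, size=(n, n)) if spec.noise_sd > 0 \
            else np.zeros((n, n))
        M = C + (E + E.T) / 2.0
        np.fill_diagonal(M, 1.0)
        out[s] = np.clip(M, -1.0, 1.0)
    if as_zscores:
        z = np.arctanh(np.clip(out, -0.999999, 0.999999))
        for s in range(m):
            np.fill_diagonal(z[s], 0.0)
        return z
    return out


def write_nifti_fixture(path, data: np.ndarray) -> None:
    """Write a small 3-D volume as NIfTI-1 with an identity affine.

    Only intended for generating tiny test inputs for the ROI extractor.
    """
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4))
    nib.save(img, path)
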