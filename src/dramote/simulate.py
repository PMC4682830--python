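"""Synthetic imbalanced datasets with controlled class overlap.

HTS assays pair a handful of actives with tens of thousands of inactives.
The generator here emulates that minority/majority structure with two
Gaussian clouds whose mean separation (in units of the common standard
deviation) controls how hard the classes are to tell apart:
``separation=0`` is pure noise, ``separation=10`` is trivially separable.
A Bernoulli "fingerprint" mode mimics the binary substructure-key feature
family of real compound data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DatasetManifest, LabeledDataset

__all__ = [
    "SimSpec",
    "gaussian_imbalance",
    "bernoulli_fingerprint",
    "table1_manifests",
    "fixture_suite",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a two-Gaussian imbalanced draw.

    separation is the Euclidean distance between class means in units of
    the (shared, isotropic) standard deviation.
    """

    n_minority: int
    n_majority: int
    dimension: int
    separation: float
    seed: int
    covariance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_minority < 1 or self.n_majority < 1:
            raise ValueError("class counts must be >= 1")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def gaussian_imbalance(spec: SimSpec) -> LabeledDataset:
    """Draw minority ~ N(mu+, s^2 I) and majority ~ N(0, s^2 I).

    The minority mean is placed along the all-ones direction at exactly
    ``separation`` (times the standard deviation) from the origin; exact
    class counts, deterministic under the seed.  Minority rows come first
    and carry label +1.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dimension
    sd = np.sqrt(spec.covariance_scale)
    mu = np.full(d, spec.separation * sd / np.sqrt(d))
    X_min = rng.normal(size=(spec.n_minority, d)) * sd + mu
    X_maj = rng.normal(size=(spec.n_majority, d)) * sd
    X = np.vstack([X_min, X_maj])
    y = np.concatenate(
        [np.ones(spec.n_minority, dtype=int), -np.ones(spec.n_majority, dtype=int)]
    )
    return LabeledDataset(X, y, meta={"sim_spec": spec})


def bernoulli_fingerprint(
    n_minority: int,
    n_majority: int,
    n_bits: int,
    p_active: float | np.ndarray,
    p_inactive: float | np.ndarray,
    seed: int,
) -> LabeledDataset:
    """Binary fingerprint-like features: per-class independent bit
    probabilities.  Actives first, label +1."""
    rng = np.random.default_rng(seed)
    pa = np.broadcast_to(np.asarray(p_active, dtype=float), (n_bits,))
    pi = np.broadcast_to(np.asarray(p_inactive, dtype=float), (n_bits,))
    X_min = (rng.random((n_minority, n_bits)) < pa).astype(float)
    X_maj = (rng.random((n_majority, n_bits)) < pi).astype(float)
    X = np.vstack([X_min, X_maj])
    y = np.concatenate([np.ones(n_minority, dtype=int), -np.ones(n_majority, dtype=int)])
    return LabeledDataset(X, y)


#: (name, target, minority size, majority size) of the nine benchmark assays.
_TABLE1_ROWS = (
    ("BenchSet", "Luciferase [Photuris pennsylvanica]", 487, 184154),
    ("AID 596", "Microtubule-associated protein tau [Homo sapiens]", 1391, 66726),
    ("AID 618", "Matrix metalloproteinase 1 [Homo sapiens]", 537, 86197),
    ("AID 644", "Rho-associated protein kinase 2 [Homo sapiens]", 67, 139),
    ("AID 886", "HADH2 chain B [Homo sapiens]", 2463, 64616),
    ("AID 899", "Cytochrome P450 2C19 precursor [Homo sapiens]", 1901, 6443),
    ("AID 938", "Thyroid stimulating hormone receptor [Homo sapiens]", 1794, 60806),
    ("AID 743042", "Androgen receptor [Homo sapiens]", 674, 6939),
    ("AID 743288", "HEK293 cell line", 95, 2128),
)


def table1_manifests() -> list[DatasetManifest]:
    """Manifests of the nine published benchmark assays (class sizes only)."""
    return [
        DatasetManifest(name=n, target_name=t, minority_size=mi, majority_size=ma)
        for n, t, mi, ma in _TABLE1_ROWS
    ]


def fixture_suite() -> dict[str, LabeledDataset]:
    """Deterministic tiny datasets used across the test suite.

    - ``collinear_pair``: two minority points on the main diagonal, so any
      interpolated synthetic point must be collinear with them.
    - ``one_hot_risk``: one minority point buried inside the majority blob
      (certain to be misclassified) and four safely clustered ones, for
      importance-weighting checks.
    - ``separable``: ~10-sigma separated Gaussians; any sane classifier is
      perfect.
    - ``gsvmru_1d``: one positive at +1 and negatives at -1, -2, -3; the
      margin-defining negative is -1.
    """
    collinear = LabeledDataset(
        X=np.array(
            [[0.0, 0.0], [2.0, 2.0], [10.0, -10.0], [11.0, -10.0], [10.0, -11.0]]
        ),
        y=np.array([1, 1, -1, -1, -1]),
    )

    rng = np.random.default_rng(20151214)
    maj = rng.normal(scale=0.5, size=(40, 2))
    min_far = np.array(
        [
            [10.0, 10.0], [10.4, 10.0], [10.0, 10.4],
            [10.4, 10.4], [10.2, 10.2], [9.8, 10.2],
        ]
    )
    min_risky = np.array([[0.0, 0.0]])
    one_hot = LabeledDataset(
        X=np.vstack([min_risky, min_far, maj]),
        y=np.concatenate([np.ones(7, dtype=int), -np.ones(40, dtype=int)]),
    )

    separable = gaussian_imbalance(
        SimSpec(n_minority=20, n_majority=100, dimension=2, separation=10.0, seed=7)
    )

    gsvmru = LabeledDataset(
        X=np.array([[1.0], [-1.0], [-2.0], [-3.0]]),
        y=np.array([1, -1, -1, -1]),
    )

    return {
        "collinear_pair": collinear,
        "one_hot_risk": one_hot,
        "separable": separable,
        "gsvmru_1d": gsvmru,
    }
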