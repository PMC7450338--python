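"""Synthetic fixtures: benchmark objectives for the continuous optimizer and
two-class datasets with known informative structure for the feature selector.

The classification generator emulates the structure of small-sample omics
data: a handful of class-separating (informative) columns, optional
redundant columns that are noisy linear combinations of the informative
ones (mirroring co-expression), and the remainder pure Gaussian noise.
Ground-truth column indices are recorded so recovery experiments can score
a selector against the truth — something real microarray data cannot offer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import ConfigurationError, ObjectiveSpec

BENCHMARK_BOUNDS = {
    "sphere": (-5.0, 5.0),
    "rastrigin": (-5.12, 5.12),
    "rosenbrock": (-5.0, 10.0),
}


def _sphere(x: np.ndarray, _rng=None) -> float:
    return float(np.sum(x**2))


def _rastrigin(x: np.ndarray, _rng=None) -> float:
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray, _rng=None) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


_BENCHMARKS = {"sphere": _sphere, "rastrigin": _rastrigin, "rosenbrock": _rosenbrock}


def make_benchmark(name: str, d: int, bounds: Optional[Tuple[float, float]] = None) -> ObjectiveSpec:
    """Standard closed-form test objective with a known global minimum."""
    if name not in _BENCHMARKS:
        raise ConfigurationError(f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARKS)}")
    if d < 1:
        raise ConfigurationError("dimension must be >= 1")
    lo, hi = bounds if bounds is not None else BENCHMARK_BOUNDS[name]
    return ObjectiveSpec(
        d=d, lower=np.full(d, lo), upper=np.full(d, hi), func=_BENCHMARKS[name], name=name
    )


@dataclass
class SyntheticSpec:
    """Recipe for a two-class dataset with planted informative features.

    ``class_sep`` is the between-class mean shift of each informative column
    in within-class standard-deviation units (default 3, a strong univariate
    effect typical of top differentially expressed genes); ``noise_sd`` is
    the residual noise added to redundant columns.
    """

    n_samples: int = 200
    n_features: int = 100
    n_informative: int = 5
    n_redundant: int = 0
    class_sep: float = 3.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ConfigurationError("informative + redundant exceeds total features")
        if self.n_informative < 1:
            raise ConfigurationError("need at least one informative feature")
        if self.n_samples < 4:
            raise ConfigurationError("need at least 4 samples (2 per class)")


@dataclass
class SyntheticDataset:
    """Generated data plus its ground truth."""

    X: np.ndarray
    y: np.ndarray
    informative: np.ndarray  # column indices after shuffling
    redundant: np.ndarray
    spec: SyntheticSpec


def make_classification(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a balanced two-class dataset from a spec.

    Informative columns are class-conditional Gaussians with means
    ``-class_sep/2`` and ``+class_sep/2`` (unit variance); redundant columns
    are random linear combinations of the informative ones plus
    ``noise_sd``-scaled Gaussian noise; all remaining columns are pure
    standard-normal noise.  Columns are shuffled, and the post-shuffle
    ground-truth indices are returned.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n1 = n // 2
    y = np.zeros(n, dtype=int)
    y[n1:] = 1

    shift = np.where(y == 1, spec.class_sep / 2.0, -spec.class_sep / 2.0)
    informative = rng.standard_normal((n, spec.n_informative)) + shift[:, None]

    blocks = [informative]
    if spec.n_redundant > 0:
        coeffs = rng.standard_normal((spec.n_informative, spec.n_redundant))
        coeffs /= np.linalg.norm(coeffs, axis=0, keepdims=True)
        redundant = informative @ coeffs + spec.noise_sd * rng.standard_normal(
            (n, spec.n_redundant)
        )
        blocks.append(redundant)
    n_noise = p - spec.n_informative - spec.n_redundant
    if n_noise > 0:
        blocks.append(rng.standard_normal((n, n_noise)))
    X = np.concatenate(blocks, axis=1)

    perm = rng.permutation(p)
    X = X[:, perm]
    inverse = np.argsort(perm)
    info_idx = np.sort(inverse[: spec.n_informative])
    red_idx = np.sort(inverse[spec.n_informative : spec.n_informative + spec.n_redundant])

    # shuffle rows so folds are not class-ordered
    row_perm = rng.permutation(n)
    return SyntheticDataset(X[row_perm], y[row_perm], info_idx, red_idx, spec)


#: (n_features, n_samples) shapes of the six benchmark biomedical datasets
#: commonly used for two-class wrapper feature selection: breast-cancer
#: prognosis/diagnosis, SPECTF heart, ovarian cancer, CNS, and colon.
TABLE_SHAPES = [(33, 198), (30, 569), (44, 267), (4000, 216), (7129, 60), (2000, 62)]


def emulate_table1_shapes(scale: float = 1.0) -> list[SyntheticSpec]:
    """Specs matching the six benchmark dataset shapes.

    ``scale`` < 1 shrinks the two widest feature spaces (7129 and 4000
    columns) for desk-scale experiments; the other shapes are kept as is.
    """
    largest = sorted((s[0] for s in TABLE_SHAPES), reverse=True)[:2]
    specs = []
    for i, (p, n) in enumerate(TABLE_SHAPES):
        if p in largest and scale != 1.0:
            p = max(int(round(p * scale)), 10)
        specs.append(
            SyntheticSpec(
                n_samples=n,
                n_features=p,
                n_informative=min(5, p),
                n_redundant=0,
                seed=i,
            )
        )
    return specs
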