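"""Synthetic data generators mirroring the study's designs.

Two generators: grouped binomial dose-response bioassays with a probit link
(WHO-style: 5 dose groups of 20 larvae), and descriptor/activity matrices
with a planted linear model plus Gaussian noise for subset-recovery tests.
All randomness flows through an explicitly seeded generator; no global
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .probit import DoseResponseDataset

__all__ = ["BioassaySimSpec", "QsarSimSpec", "gen_bioassay", "gen_qsar"]


@dataclass(frozen=True)
class BioassaySimSpec:
    lc50: float = 50.0
    slope: float = 2.5               # probits per log10 dose
    doses: tuple[float, ...] = (10.0, 25.0, 50.0, 100.0, 250.0)
    n_per_group: int = 20
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.lc50 <= 0 or self.slope <= 0:
            raise ValueError("lc50 and slope must be positive")
        if self.n_per_group < 1:
            raise ValueError("need at least one larva per group")

    def mortality(self, dose: float) -> float:
        """Noise-free expected mortality at a dose."""
        return float(stats.norm.cdf(
            self.slope * (np.log10(dose) - np.log10(self.lc50))))


def gen_bioassay(spec: BioassaySimSpec,
                 rng: np.random.Generator | None = None
                 ) -> list[DoseResponseDataset]:
    """One DoseResponseDataset per replicate; deaths ~ Binomial(n, Phi(.))."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    p = np.array([spec.mortality(d) for d in spec.doses])
    out = []
    for _ in range(spec.replicates):
        deaths = rng.binomial(spec.n_per_group, p)
        out.append(DoseResponseDataset(
            groups=tuple(
                (d, spec.n_per_group, int(k))
                for d, k in zip(spec.doses, deaths)),
            control=(spec.n_per_group, 0),
        ))
    return out


@dataclass(frozen=True)
class QsarSimSpec:
    n_compounds: int = 50
    n_descriptors: int = 20
    planted: tuple[int, ...] = (0, 1, 2)
    coefficients: tuple[float, ...] = (1.0, -0.8, 0.6)
    intercept: float = 0.0
    noise_sd: float = 0.5
    correlation: float = 0.0         # equicorrelation between descriptors
    seed: int = 0

    def __post_init__(self):
        if len(self.planted) != len(self.coefficients):
            raise ValueError("planted subset and coefficients disagree")
        if any(not 0 <= j < self.n_descriptors for j in self.planted):
            raise ValueError("planted index out of descriptor range")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        p = self.n_descriptors
        if not -1.0 / (p - 1) < self.correlation < 1.0:
            raise ValueError("equicorrelation level is not positive definite")


@dataclass(frozen=True)
class QsarTruth:
    planted: tuple[int, ...]
    planted_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    realized_r2: float


def gen_qsar(spec: QsarSimSpec,
             rng: np.random.Generator | None = None
             ) -> tuple[pd.DataFrame, pd.Series, QsarTruth]:
    """Correlated-normal descriptors, planted linear response, truth record."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    cov = np.full((p, p), spec.correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, p)) @ chol.T
    names = [f"d{j:02d}" for j in range(p)]
    df = pd.DataFrame(X, columns=names,
                      index=pd.RangeIndex(1, n + 1, name="id"))
    signal = spec.intercept + sum(
        c * X[:, j] for j, c in zip(spec.planted, spec.coefficients))
    noise = rng.normal(0.0, spec.noise_sd, size=n)
    y = pd.Series(signal + noise, index=df.index, name="y")
    var_sig = float(np.var(signal))
    var_tot = float(np.var(signal + noise))
    truth = QsarTruth(
        planted=tuple(spec.planted),
        planted_names=tuple(names[j] for j in spec.planted),
        coefficients=tuple(spec.coefficients),
        intercept=spec.intercept,
        realized_r2=var_sig / var_tot if var_tot > 0 else 1.0,
    )
    return df, y, truth
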