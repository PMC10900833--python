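"""Drug parameter library and virtual-patient cohort sampling.

The five study antibiotics (cefepime, ceftazidime, imipenem, meropenem,
piperacillin) plus the companion inhibitor tazobactam are described by
population distributions of one-compartment PK parameters reported for
critically ill patients on kidney replacement therapy (KRT):

* volume of distribution per kg body weight,
* unbound (free) fraction ``fu``,
* non-renal clearance ``CL_NR`` (the only elimination route off KRT in
  anuric patients),
* saturation coefficients ``SA`` at dialysate flows of 300, 100 and
  50 mL/min, and a sieving coefficient ``SC`` at an ultrafiltrate flow of
  5 mL/min (extraction coefficients multiplying effluent flow to give
  transmembrane clearance).

Every parameter is summarised as arithmetic mean +/- SD with a plausible
range, and virtual patients are drawn independently per parameter from a
log-normal distribution moment-matched to that mean/SD, truncated to the
range by rejection resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "ParamSpec",
    "DrugModel",
    "VirtualPatient",
    "Cohort",
    "BODY_WEIGHT",
    "load_drug_library",
    "lognormal_underlying_params",
    "sample_truncated_lognormal",
    "sample_cohort",
]

#: Minimum acceptance probability of a truncation window before the sampler
#: declares the (mean, sd, range) combination internally inconsistent.
MIN_ACCEPTANCE_PROBABILITY = 1e-6


@dataclass(frozen=True)
class ParamSpec:
    """Arithmetic mean +/- SD with truncation range for one PK parameter.

    ``low``/``high`` bound the sampled values; a non-positive ``low`` means
    "no lower truncation" because the log-normal support already excludes 0.
    """

    mean: float
    sd: float
    low: float = 0.0
    high: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.low < self.high:
            raise ValueError(f"low must be < high, got [{self.low}, {self.high}]")
        if not (self.low <= self.mean <= self.high):
            raise ValueError(
                f"mean {self.mean} outside range [{self.low}, {self.high}]"
            )


@dataclass(frozen=True)
class DrugModel:
    """PK parameter distributions plus PD and safety targets for one drug.

    ``mic`` is the P. aeruginosa susceptibility breakpoint (for tazobactam
    it holds the 4 mg/L free-concentration threshold).  ``ft_fraction`` is
    the required fraction of each 24-h day with free concentration above
    target.  ``toxicity_threshold`` is a total plasma concentration linked
    to neurotoxicity risk; ``None`` when no threshold is defined.
    ``companion``/``companion_dose_ratio`` link piperacillin to tazobactam
    (8:1 by product formulation, e.g. 4.5 g = 4 g + 0.5 g).
    """

    name: str
    vd_per_kg: ParamSpec
    fu: ParamSpec
    cl_nr: ParamSpec
    sa_by_qd: Mapping[int, ParamSpec]
    sc_uf: ParamSpec
    mic: float
    ft_fraction: float
    toxicity_threshold: Optional[float] = None
    mic_multiplier_targets: Tuple[int, ...] = (1, 4)
    companion: Optional[str] = None
    companion_dose_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ft_fraction not in (0.40, 0.50, 0.60):
            raise ValueError(f"unexpected ft_fraction {self.ft_fraction}")
        if self.mic <= 0:
            raise ValueError("mic must be > 0")
        if self.toxicity_threshold is not None and self.toxicity_threshold <= 0:
            raise ValueError("toxicity_threshold must be > 0 when defined")


@dataclass(frozen=True)
class VirtualPatient:
    """One sampled parameter vector; ``vd = vd_per_kg * body_weight`` (L)."""

    body_weight: float
    vd: float
    fu: float
    cl_nr: float
    sa: Mapping[int, float]
    sc: float
    rng_id: int = 0


#: Body weight (kg) of critically ill KRT patients, shared by all drugs.
BODY_WEIGHT = ParamSpec(mean=88.0, sd=26.0, low=40.0, high=177.0)

FRACTION = dict(low=0.0, high=1.0)

_LIBRARY: Dict[str, DrugModel] = {
    "cefepime": DrugModel(
        name="cefepime",
        vd_per_kg=ParamSpec(0.45, 0.25, 0.25, 1.11),
        fu=ParamSpec(0.79, 0.09, **FRACTION),
        cl_nr=ParamSpec(24.6, 19.4, 0.0, 66.8),
        sa_by_qd={
            300: ParamSpec(0.45, 0.09, **FRACTION),
            100: ParamSpec(0.68, 0.14, **FRACTION),
            50: ParamSpec(0.75, 0.15, **FRACTION),
        },
        sc_uf=ParamSpec(0.82, 0.16, **FRACTION),
        mic=8.0,
        ft_fraction=0.60,
        toxicity_threshold=20.0,
    ),
    "ceftazidime": DrugModel(
        name="ceftazidime",
        vd_per_kg=ParamSpec(0.29, 0.20, 0.17, 1.10),
        fu=ParamSpec(0.86, 0.08, **FRACTION),
        cl_nr=ParamSpec(20.8, 7.0, 10.1, 37.7),
        sa_by_qd={
            300: ParamSpec(0.34, 0.06, **FRACTION),
            100: ParamSpec(0.58, 0.11, **FRACTION),
            50: ParamSpec(0.73, 0.15, **FRACTION),
        },
        sc_uf=ParamSpec(1.0, 0.20, **FRACTION),
        mic=8.0,
        ft_fraction=0.60,
        toxicity_threshold=64.0,
    ),
    "imipenem": DrugModel(
        name="imipenem",
        vd_per_kg=ParamSpec(0.36, 0.15, 0.11, 0.75),
        fu=ParamSpec(0.80, 0.16, **FRACTION),
        cl_nr=ParamSpec(89.2, 31.9, 27.1, 160.0),
        sa_by_qd={
            300: ParamSpec(0.34, 0.07, **FRACTION),
            100: ParamSpec(0.63, 0.12, **FRACTION),
            50: ParamSpec(0.82, 0.16, **FRACTION),
        },
        sc_uf=ParamSpec(0.82, 0.16, **FRACTION),
        mic=2.0,
        ft_fraction=0.40,
        toxicity_threshold=16.0,
    ),
    "meropenem": DrugModel(
        name="meropenem",
        vd_per_kg=ParamSpec(0.39, 0.18, 0.08, 1.07),
        fu=ParamSpec(0.98, 0.16, **FRACTION),
        cl_nr=ParamSpec(38.3, 25.6, 0.0, 104.8),
        sa_by_qd={
            300: ParamSpec(0.37, 0.07, **FRACTION),
            100: ParamSpec(0.65, 0.13, **FRACTION),
            50: ParamSpec(0.83, 0.16, **FRACTION),
        },
        sc_uf=ParamSpec(0.98, 0.20, **FRACTION),
        mic=2.0,
        ft_fraction=0.40,
        toxicity_threshold=64.0,
    ),
    "piperacillin": DrugModel(
        name="piperacillin",
        vd_per_kg=ParamSpec(0.4, 0.21, 0.12, 1.72),
        fu=ParamSpec(0.81, 0.10, **FRACTION),
        cl_nr=ParamSpec(45.7, 38.3, 0.0, 192.0),
        sa_by_qd={
            300: ParamSpec(0.31, 0.06, **FRACTION),
            100: ParamSpec(0.46, 0.09, **FRACTION),
            50: ParamSpec(0.55, 0.11, **FRACTION),
        },
        sc_uf=ParamSpec(0.87, 0.17, **FRACTION),
        mic=16.0,
        ft_fraction=0.50,
        toxicity_threshold=157.0,
        companion="tazobactam",
        companion_dose_ratio=8.0,
    ),
    "tazobactam": DrugModel(
        name="tazobactam",
        vd_per_kg=ParamSpec(0.5, 0.37, 0.11, 2.13),
        fu=ParamSpec(0.74, 0.27, **FRACTION),
        cl_nr=ParamSpec(38.3, 66.2, 0.0, 381.0),
        sa_by_qd={
            300: ParamSpec(0.33, 0.07, **FRACTION),
            100: ParamSpec(0.51, 0.10, **FRACTION),
            50: ParamSpec(0.63, 0.13, **FRACTION),
        },
        sc_uf=ParamSpec(1.0, 0.20, **FRACTION),
        mic=4.0,  # fixed free-concentration threshold, not a MIC breakpoint
        ft_fraction=0.50,
        toxicity_threshold=None,
        mic_multiplier_targets=(1,),
    ),
}


def load_drug_library() -> Dict[str, DrugModel]:
    """Return the built-in library of the six drug models.

    A fresh dict is returned on each call so callers may override entries
    (e.g. from a YAML config) without mutating the package defaults.
    """
    return dict(_LIBRARY)


def lognormal_underlying_params(mean: float, sd: float) -> Tuple[float, float]:
    """Normal-scale (mu, sigma) of the log-normal moment-matched to (mean, sd).

    sigma^2 = ln(1 + (sd/mean)^2), mu = ln(mean) - sigma^2 / 2, so that the
    log-normal's arithmetic mean and SD equal the supplied values.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0 for a log-normal fit, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_truncated_lognormal(
    spec: ParamSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from the moment-matched, range-truncated log-normal.

    Truncation is by rejection resampling, so no probability mass piles up
    at the bounds; post-truncation moments therefore deviate slightly from
    the nominal (mean, sd).  ``sd == 0`` degenerates to the constant mean.

    Raises
    ------
    ValueError
        If the truncation window captures less than ``1e-6`` of the
        distribution's mass (an internally inconsistent specification).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.sd == 0.0:
        return np.full(n, spec.mean)
    mu, sigma = lognormal_underlying_params(spec.mean, spec.sd)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    lo = spec.low if spec.low > 0 else 0.0
    accept_p = dist.cdf(spec.high) - dist.cdf(lo)
    if accept_p < MIN_ACCEPTANCE_PROBABILITY:
        raise ValueError(
            f"truncation window [{spec.low}, {spec.high}] captures "
            f"{accept_p:.2e} of the log-normal mass for mean={spec.mean}, "
            f"sd={spec.sd}; specification is inconsistent"
        )
    out = np.empty(n)
    filled = 0
    # oversample to keep the expected number of rounds near one
    while filled < n:
        need = n - filled
        batch = max(64, int(need / accept_p * 1.2))
        draws = np.exp(rng.normal(mu, sigma, size=batch))
        kept = draws[(draws >= lo) & (draws <= spec.high)]
        take = min(need, kept.size)
        out[filled : filled + take] = kept[:take]
        filled += take
    return out


# fixed order in which per-parameter substreams are spawned; appending new
# parameters keeps existing draws reproducible
_PARAM_ORDER = ("body_weight", "vd_per_kg", "fu", "cl_nr", "sa300", "sa100", "sa50", "sc")


@dataclass(frozen=True)
class Cohort:
    """A seeded cohort of virtual patients for one drug, stored columnar.

    Arrays are aligned by patient index; ``vd`` is in litres
    (``vd_per_kg * body_weight``), clearances in mL/min.
    """

    drug: DrugModel
    seed: object
    body_weight: np.ndarray
    vd: np.ndarray
    fu: np.ndarray
    cl_nr: np.ndarray
    sa: Mapping[int, np.ndarray]
    sc: np.ndarray

    @property
    def n(self) -> int:
        return self.body_weight.size

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> VirtualPatient:
        return VirtualPatient(
            body_weight=float(self.body_weight[i]),
            vd=float(self.vd[i]),
            fu=float(self.fu[i]),
            cl_nr=float(self.cl_nr[i]),
            sa={qd: float(v[i]) for qd, v in self.sa.items()},
            sc=float(self.sc[i]),
            rng_id=i,
        )

    def __iter__(self) -> Iterator[VirtualPatient]:
        return (self[i] for i in range(self.n))

    @property
    def patients(self) -> Tuple[VirtualPatient, ...]:
        return tuple(self)


def sample_cohort(drug: DrugModel, n: int, seed) -> Cohort:
    """Sample ``n`` virtual patients for ``drug``, deterministically per seed.

    Each parameter is drawn from its own substream (spawned in a fixed
    order from ``seed``), so all parameters are mutually independent and
    the cohort is bit-identical under the same seed.  ``seed`` may be an
    integer or a ``numpy.random.SeedSequence``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(_PARAM_ORDER))
    rngs = {name: np.random.default_rng(c) for name, c in zip(_PARAM_ORDER, children)}

    bw = sample_truncated_lognormal(BODY_WEIGHT, n, rngs["body_weight"])
    vd_kg = sample_truncated_lognormal(drug.vd_per_kg, n, rngs["vd_per_kg"])
    fu = sample_truncated_lognormal(drug.fu, n, rngs["fu"])
    cl_nr = sample_truncated_lognormal(drug.cl_nr, n, rngs["cl_nr"])
    sa = {
        qd: sample_truncated_lognormal(spec, n, rngs[f"sa{qd}"])
        for qd, spec in drug.sa_by_qd.items()
    }
    sc = sample_truncated_lognormal(drug.sc_uf, n, rngs["sc"])
    return Cohort(
        drug=drug,
        seed=seed,
        body_weight=bw,
        vd=vd_kg * bw,
        fu=fu,
        cl_nr=cl_nr,
        sa=sa,
        sc=sc,
    )
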