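"""Synthetic size-at-age and reader-matrix generators.

Emulates the statistical structure of vertebral-ageing field data for four
sympatric tropical stingrays, plus the idealised designs used to compare
estimators: a well-represented design (m observations at each of A integer
age classes) and data-poor subsamples of it (small random n, or age-range
truncation followed by random sampling).

Sizes are drawn as the species' mean growth curve (two-parameter von
Bertalanffy by default) plus additive Gaussian observation noise, truncated
to positive sizes; ages sit on a half-year grid mirroring the field protocol
of adding 0.5 yr for a forming edge band.  The default noise scale is 4% of
the asymptotic size — the residual scatter is configurable, and this level
matches the visual spread of real size-at-age plots for these species.

Every generator is a pure function of its arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .models import GrowthParams, SizeAtAgeRecord, predict_size
from .precision import ReaderMatrix

__all__ = [
    "SpeciesTemplate",
    "SPECIES_PRESETS",
    "generate_sample",
    "generate_full_design",
    "data_poor_subsample",
    "generate_reader_matrix",
]

#: observed share of readability scores 1 / 2 / 3 across all vertebrae
READABILITY_PROPORTIONS = (50 / 170, 75 / 170, 45 / 170)


@dataclass(frozen=True)
class SpeciesTemplate:
    """Generating model and sampling frame for one species.

    ``noise_sd`` is the additive Gaussian observation sd in cm; when None it
    defaults to ``0.04 * w_inf``.  ``noise_cv`` switches to proportional
    noise (sd = noise_cv * predicted size) instead.
    """

    name: str
    w_inf: float
    k: float
    w0: float
    age_min: float
    age_max: float
    n: int
    model: str = "vbgf2"
    noise_sd: Optional[float] = None
    noise_cv: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.age_min < self.age_max <= 50):
            raise ValueError("age range must satisfy 0 <= min < max <= 50")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd is not None and not (self.noise_sd > 0):
            raise ValueError("noise_sd must be > 0")
        if self.noise_cv is not None and not (self.noise_cv > 0):
            raise ValueError("noise_cv must be > 0")

    @property
    def params(self) -> GrowthParams:
        if self.model == "vbgf":
            raise ValueError("templates use size-at-birth models; vbgf has no w0")
        return GrowthParams(self.model, w_inf=self.w_inf, k=self.k, w0=self.w0)

    def sd_at(self, predicted: np.ndarray) -> np.ndarray:
        if self.noise_cv is not None:
            return self.noise_cv * predicted
        sd = self.noise_sd if self.noise_sd is not None else 0.04 * self.w_inf
        return np.full_like(predicted, sd)


#: the four study species: growth at the published Bayesian posterior
#: medians, sampling frames from the observed age ranges and sample sizes,
#: w0 = the species' minimum observed disc width.
SPECIES_PRESETS = {
    "H_uarnak": SpeciesTemplate("H_uarnak", w_inf=149.0, k=0.12, w0=25.0,
                                age_min=1.0, age_max=25.0, n=19),
    "N_kuhlii": SpeciesTemplate("N_kuhlii", w_inf=42.0, k=0.38, w0=17.0,
                                age_min=1.5, age_max=13.0, n=34),
    "P_atrus": SpeciesTemplate("P_atrus", w_inf=156.0, k=0.16, w0=36.5,
                               age_min=1.0, age_max=27.0, n=32),
    "T_lymma": SpeciesTemplate("T_lymma", w_inf=33.0, k=0.24, w0=14.0,
                               age_min=1.0, age_max=11.0, n=40),
}


def _noisy_records(template, ages, rng) -> list[SizeAtAgeRecord]:
    pred = np.asarray(predict_size(template.params, ages), dtype=float)
    sd = template.sd_at(pred)
    sizes = pred + rng.normal(0.0, 1.0, size=len(ages)) * sd
    bad = sizes <= 0  # redraw until strictly positive (truncated noise)
    while np.any(bad):
        sizes[bad] = pred[bad] + rng.normal(0.0, 1.0, size=int(bad.sum())) * sd[bad]
        bad = sizes <= 0
    return [
        SizeAtAgeRecord(species=template.name, age=float(a), disc_width=float(s))
        for a, s in zip(ages, sizes)
    ]


def generate_sample(template: SpeciesTemplate, seed: int) -> list[SizeAtAgeRecord]:
    """Draw ``template.n`` records: ages uniform on the template range
    (rounded to the 0.5-yr grid), sizes from the growth curve plus noise."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(template.age_min, template.age_max, size=template.n)
    ages = np.round(ages * 2.0) / 2.0
    return _noisy_records(template, ages, rng)


def generate_full_design(
    n_ages: int, per_age: int, template: SpeciesTemplate, seed: int
) -> list[SizeAtAgeRecord]:
    """Well-represented design: ``per_age`` observations at each integer age
    1..n_ages (``n_ages * per_age`` records, flat age histogram)."""
    if n_ages < 2 or per_age < 1:
        raise ValueError("need n_ages >= 2 and per_age >= 1")
    rng = np.random.default_rng(seed)
    ages = np.repeat(np.arange(1, n_ages + 1, dtype=float), per_age)
    return _noisy_records(template, ages, rng)


def data_poor_subsample(
    records: Sequence[SizeAtAgeRecord], scheme: str, n: int, seed: int
) -> list[SizeAtAgeRecord]:
    """Data-poor sampling from a full design.

    ``random_n``: simple random sample of n without replacement.
    ``truncate_old`` / ``truncate_young``: drop the oldest / youngest third
    of the observed age classes first, then sample n at random.
    """
    if scheme not in ("random_n", "truncate_old", "truncate_young"):
        raise ValueError(f"unknown scheme {scheme!r}")
    pool = list(records)
    if scheme != "random_n":
        classes = sorted({r.age for r in pool})
        n_drop = -(-len(classes) // 3)  # ceil: removes a full third of classes
        dropped = set(classes[-n_drop:]) if scheme == "truncate_old" else set(classes[:n_drop])
        pool = [r for r in pool if r.age not in dropped]
    if n > len(pool):
        raise ValueError(f"requested n={n} exceeds {len(pool)} available records")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_reader_matrix(
    true_ages: Sequence[float],
    epsilon: float,
    n_readers: int = 3,
    readability_proportions: Sequence[float] = READABILITY_PROPORTIONS,
    seed: int = 0,
) -> ReaderMatrix:
    """Simulate blind multi-reader band counts.

    Each read equals the true age plus a +/-1 band miscount with probability
    ``epsilon`` (sign equally likely, floored at age 0); per-animal
    readability scores 1..3 are drawn from ``readability_proportions``.
    """
    if not (0 <= epsilon < 1):
        raise ValueError("epsilon must be in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_ages, dtype=float)
    n = len(truth)
    miss = rng.random((n, n_readers)) < epsilon
    sign = rng.choice([-1.0, 1.0], size=(n, n_readers))
    reads = np.maximum(truth[:, None] + miss * sign, 0.0)
    props = np.asarray(readability_proportions, dtype=float)
    props = props / props.sum()
    readability = rng.choice([1, 2, 3], size=n, p=props)
    return ReaderMatrix(
        animal_ids=[f"animal_{i + 1}" for i in range(n)],
        reads=reads,
        readability=readability,
    )


def with_noise_fraction(template: SpeciesTemplate, fraction: float) -> SpeciesTemplate:
    """Copy of ``template`` with additive noise sd set to ``fraction * w_inf``."""
    return replace(template, noise_sd=fraction * template.w_inf, noise_cv=None)
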