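"""Presence-only sample assessment: PTIT counts and the TPI posterior.

Two metrics, both deliberately blind to absences so that collection and
sorting losses cannot produce a wrong call, only "no conclusion":

* PTIT (presence of threshold indicator taxa): a sample is called
  unimpaired (impaired) when it contains at least k distinct indicator
  taxa of that direction.

* TPI (threshold probability of impairment): a three-class naive-Bayes
  posterior over {non-impacted, slightly impacted, impaired} computed from
  the indicator taxa *present* in the sample,

      P(class | sample) ∝ P(class) · prod_i P(IT_i | class),

  where the product runs over every indicator taxon found in the sample
  (both directions) and P(IT|class) is its occurrence frequency in that
  class.  A sample with no indicator taxa returns the priors (empty
  product).  The call compares the non-impacted or impaired posterior
  component against a probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan
from typing import Iterable, Sequence

from .taxonomy import IndicatorRegistry, _norm
from .training import CategoryPriors, FrequencyTable, SampleRecord

UNIMPAIRED = "unimpaired"
IMPAIRED = "impaired"
NO_CONCLUSION = "no-conclusion"


@dataclass(frozen=True)
class TpiPosterior:
    """Three-class posterior (non-impacted, slightly impacted, impaired).

    ``defined`` is False when every class assigns the observed taxa zero
    likelihood (a 0/0 posterior), in which case the components are NaN and
    any threshold call is "no conclusion".
    """

    p_nonimpacted: float
    p_slight: float
    p_impaired: float
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined:
            total = self.p_nonimpacted + self.p_slight + self.p_impaired
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"posterior components sum to {total}, expected 1")

    @classmethod
    def undefined(cls) -> "TpiPosterior":
        return cls(float("nan"), float("nan"), float("nan"), defined=False)


@dataclass(frozen=True)
class AssessmentResult:
    sample_id: str
    n_unimpaired_indicators: int
    n_impaired_indicators: int
    ptit_call: str
    posterior: TpiPosterior
    tpi_call: str
    flags: tuple[str, ...] = ()


def count_indicators(taxa: Iterable[str],
                     registry: IndicatorRegistry) -> tuple[int, int]:
    """Counts of distinct unimpaired- and impaired-direction indicator taxa
    present; non-indicator taxa are ignored and duplicates count once."""
    n_unimp = n_imp = 0
    for label in {_norm(t) for t in taxa}:
        direction = registry.direction(label)
        if direction == UNIMPAIRED:
            n_unimp += 1
        elif direction == IMPAIRED:
            n_imp += 1
    return n_unimp, n_imp


def ptit_assess(taxa: Iterable[str], registry: IndicatorRegistry,
                k_unimpaired: int = 6, k_impaired: int = 6) -> str:
    """PTIT call: unimpaired (impaired) when at least k distinct indicators
    of that direction are present, inclusive; otherwise no conclusion.
    Should both directions trigger, the result is no-conclusion."""
    if k_unimpaired < 1 or k_impaired < 1:
        raise ValueError("PTIT thresholds must be >= 1")
    n_unimp, n_imp = count_indicators(taxa, registry)
    hit_unimp = n_unimp >= k_unimpaired
    hit_imp = n_imp >= k_impaired
    if hit_unimp and hit_imp:
        return NO_CONCLUSION
    if hit_unimp:
        return UNIMPAIRED
    if hit_imp:
        return IMPAIRED
    return NO_CONCLUSION


def tpi_posterior(taxa: Iterable[str], freq: FrequencyTable,
                  priors: CategoryPriors, registry: IndicatorRegistry,
                  smoothing: float = 0.0) -> TpiPosterior:
    """Three-class naive-Bayes posterior from the present indicator taxa.

    Every registry taxon present in the sample enters the product, both
    directions; absent taxa contribute nothing.  Zero frequencies are used
    as-is by default, so a present taxon never seen in a class zeroes that
    class's posterior.  ``smoothing`` > 0 applies additive smoothing
    f -> (f + a) / (1 + 2a) to every frequency, guarding the all-zero
    case at the cost of no longer reproducing the exact table arithmetic.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    terms = list(priors.as_tuple())
    for label in sorted({_norm(t) for t in taxa}):
        if registry.direction(label) is None:
            continue
        if label not in freq:
            raise ValueError(f"indicator taxon {label!r} has no frequencies")
        for j, f in enumerate(freq.freq(label)):
            if smoothing > 0:
                f = (f + smoothing) / (1.0 + 2.0 * smoothing)
            terms[j] *= f
    denom = sum(terms)
    if denom == 0.0:
        return TpiPosterior.undefined()
    return TpiPosterior(terms[0] / denom, terms[1] / denom, terms[2] / denom)


def tpi_assess(posterior: TpiPosterior, threshold: float = 0.90) -> str:
    """TPI call: unimpaired when the non-impacted posterior meets the
    probability threshold (inclusive), impaired when the impaired posterior
    does; otherwise (or for an undefined posterior) no conclusion."""
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("TPI threshold must lie in [0.5, 1]")
    if not posterior.defined:
        return NO_CONCLUSION
    hit_unimp = posterior.p_nonimpacted >= threshold
    hit_imp = posterior.p_impaired >= threshold
    if hit_unimp and hit_imp:  # only possible at threshold exactly 0.5
        return NO_CONCLUSION
    if hit_unimp:
        return UNIMPAIRED
    if hit_imp:
        return IMPAIRED
    return NO_CONCLUSION


def assess_sample(sample: SampleRecord, registry: IndicatorRegistry,
                  freq: FrequencyTable, priors: CategoryPriors,
                  k_unimpaired: int = 6, k_impaired: int = 6,
                  tpi_threshold: float = 0.90,
                  smoothing: float = 0.0) -> AssessmentResult:
    """Score one sample with both metrics at the configured thresholds."""
    n_unimp, n_imp = count_indicators(sample.taxa, registry)
    flags: list[str] = []
    ptit = ptit_assess(sample.taxa, registry, k_unimpaired, k_impaired)
    if ptit == NO_CONCLUSION and n_unimp >= k_unimpaired and n_imp >= k_impaired:
        flags.append("ptit-conflict")
    posterior = tpi_posterior(sample.taxa, freq, priors, registry, smoothing)
    if not posterior.defined:
        flags.append("undefined-posterior")
    tpi = tpi_assess(posterior, tpi_threshold)
    return AssessmentResult(sample.sample_id, n_unimp, n_imp, ptit,
                            posterior, tpi, tuple(flags))


def assess_samples(samples: Sequence[SampleRecord], registry: IndicatorRegistry,
                   freq: FrequencyTable, priors: CategoryPriors,
                   **kwargs) -> list[AssessmentResult]:
    return [assess_sample(s, registry, freq, priors, **kwargs) for s in samples]
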