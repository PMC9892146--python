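"""Synthetic presence/absence community data and exact analytic oracles.

The generator draws each sample's condition class from configured
proportions and then each taxon's presence independently as a Bernoulli
trial at that taxon's class-conditional occurrence frequency — exactly the
class-conditional-independence structure the naive-Bayes metric assumes.
Real macroinvertebrate communities are correlated, so simulated sweep
percentages emulate the *model*, not any particular field data set.  A
pseudo-BAP score is drawn uniformly within the class's band purely so the
category round-trips through the banding rules; it carries no ecological
signal beyond the class.

Because taxa are independent given the class, the number of indicator
taxa present follows a Poisson-binomial distribution, which gives exact
closed forms for PTIT sweep percentages and for the large-sample limit of
the Sørensen taxon contributions — the oracles the simulation is checked
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference import load_packaged_frequencies, load_packaged_priors
from .taxonomy import IndicatorRegistry
from .training import CategoryPriors, FrequencyTable, SampleRecord

_CLASS_BANDS = {  # pseudo-BAP bands; impaired spans moderate + severe
    "non": (7.5, 10.0),
    "slight": (np.nextafter(5.0, 7.5), 7.5),  # keep 5.0 itself out: BAP <= 5 is impaired
    "impaired": (0.0, 5.0),
}
_CLASSES = ("non", "slight", "impaired")


@dataclass
class GeneratorSpec:
    """Configuration of the synthetic community generator.

    Defaults reproduce the reference study conditions: class proportions
    406:728:287 (the training-set composition) and the packaged indicator
    frequencies as presence probabilities.  ``background`` adds
    non-indicator taxa with the same frequency in every class (noise taxa
    that carry no signal).  ``subsample_size`` switches on emulation of the
    100-organism random subsample: latent geometric abundances are drawn
    for present taxa and a fixed-size subsample without replacement is
    converted back to presence/absence.
    """

    n_samples: int = 1421
    proportions: tuple[float, float, float] | None = None  # (non, slight, impaired)
    frequencies: FrequencyTable | None = None
    background: Mapping[str, float] | None = None
    subsample_size: int | None = None
    mean_abundance: float = 5.0  # latent mean count per present taxon (subsample mode)
    seed: int = 0

    def resolved(self) -> tuple[tuple[float, float, float], FrequencyTable]:
        props = self.proportions
        if props is None:
            props = load_packaged_priors().as_tuple()
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions must be non-negative and sum to 1: {props}")
        freqs = self.frequencies if self.frequencies is not None \
            else load_packaged_frequencies()
        return tuple(props), freqs


def generate_dataset(spec: GeneratorSpec) -> list[SampleRecord]:
    """Draw a labelled presence/absence dataset; the seed fixes the output."""
    props, freqs = spec.resolved()
    if spec.n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(spec.seed)

    labels = sorted(freqs.labels())
    probs = np.array([freqs.freq(l) for l in labels], dtype=float)  # (T, 3)
    if spec.background:
        bg_labels = sorted(spec.background)
        bg = np.array([[spec.background[l]] * 3 for l in bg_labels], dtype=float)
        if bg.size and not ((bg >= 0) & (bg <= 1)).all():
            raise ValueError("background frequencies must lie in [0, 1]")
        labels = labels + bg_labels
        probs = np.vstack([probs, bg]) if bg.size else probs

    width = len(str(spec.n_samples))
    samples: list[SampleRecord] = []
    for i in range(spec.n_samples):
        cls_idx = rng.choice(3, p=props)
        cls = _CLASSES[cls_idx]
        present = rng.random(len(labels)) < probs[:, cls_idx]
        taxa = {labels[j] for j in np.flatnonzero(present)}
        if spec.subsample_size is not None and taxa:
            taxa = _subsample(sorted(taxa), spec.subsample_size,
                              spec.mean_abundance, rng)
        lo, hi = _CLASS_BANDS[cls]
        bap = float(rng.uniform(lo, hi))
        samples.append(SampleRecord(f"syn{i:0{width}d}", frozenset(taxa), bap=bap))
    return samples


def _subsample(taxa: Sequence[str], size: int, mean_abundance: float,
               rng: np.random.Generator) -> set[str]:
    """Random fixed-size subsample of latent geometric abundances,
    collapsed back to presence/absence."""
    counts = rng.geometric(1.0 / mean_abundance, size=len(taxa))
    total = int(counts.sum())
    if total <= size:
        return set(taxa)
    kept = rng.multivariate_hypergeometric(counts, size)
    return {t for t, k in zip(taxa, kept) if k > 0}


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli
    trials with the given probabilities (dynamic-programming convolution)."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and not ((probs >= 0) & (probs <= 1)).all():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(pmf.size + 1)
        nxt[:-1] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """Exact P(number of successes >= k)."""
    if k <= 0:
        return 1.0
    pmf = poisson_binomial_pmf(probs)
    if k >= pmf.size:
        return 0.0
    return float(pmf[k:].sum())


def expected_ptit_performance(freqs: FrequencyTable, priors: CategoryPriors,
                              registry: IndicatorRegistry, k: int,
                              direction: str = "unimpaired",
                              ) -> tuple[float, float]:
    """Closed-form PTIT sweep cell under the independence model.

    For the unimpaired direction with threshold k:
        matching = 100 * (p_NI * T_NI + p_SL * T_SL) / (p_NI + p_SL)
        type1    = 100 * p_IM * T_IM
    where T_cls is the Poisson-binomial tail P(count >= k) of the
    unimpaired-indicator frequencies in that class.  The impaired
    direction is the mirror image (using impaired-indicator frequencies).
    """
    if direction not in ("unimpaired", "impaired"):
        raise ValueError(f"unknown direction {direction!r}")
    labels = registry.labels(direction)
    cols = np.array([freqs.freq(l) for l in labels], dtype=float)
    t_non, t_sl, t_im = (poisson_binomial_tail(cols[:, j], k) for j in range(3))
    p_non, p_sl, p_im = priors.as_tuple()
    if direction == "unimpaired":
        matching = 100.0 * (p_non * t_non + p_sl * t_sl) / (p_non + p_sl)
        type1 = 100.0 * p_im * t_im
    else:
        matching = 100.0 * t_im
        type1 = 100.0 * (p_non * t_non + p_sl * t_sl)
    return matching, type1


def expected_taxon_contributions(freqs: Mapping[str, float]) -> dict[str, float]:
    """Large-sample limit of the pairwise Sørensen taxon contributions
    under independent Bernoulli presence with the given frequencies.

    For taxon t with frequency f_t, over a random sample pair the expected
    shared-presence weight is f_t^2 * E[2 / (2 + S + S')], where S and S'
    are independent Poisson-binomial counts of the *other* taxa; the
    contribution is that term normalized over all taxa.  This is the
    analytic oracle the empirical contributions converge to.
    """
    labels = sorted(freqs)
    p = np.array([freqs[l] for l in labels], dtype=float)
    raw = np.zeros(len(labels))
    for t in range(len(labels)):
        others = np.delete(p, t)
        pmf = poisson_binomial_pmf(others)
        sizes = np.arange(pmf.size)
        # E[2/(2 + S + S')] with S, S' iid Poisson-binomial
        weight = (pmf[:, None] * pmf[None, :] *
                  (2.0 / (2.0 + sizes[:, None] + sizes[None, :]))).sum()
        raw[t] = p[t] ** 2 * weight
    total = raw.sum()
    if total <= 0:
        return {l: 0.0 for l in labels}
    return {l: float(r / total) for l, r in zip(labels, raw)}
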