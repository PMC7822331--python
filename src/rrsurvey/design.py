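"""Forced-response randomization designs.

A forced response design (FRD) protects respondent privacy by letting a
chance device decide the answer: with probability ``p_forced_yes`` the
respondent must answer "yes", with probability ``p_forced_no`` "no", and
with probability ``p_genuine`` they answer the sensitive question
truthfully.  The device induces an affine misclassification line

    lambda = c + d * pi,        c = p_forced_yes,  d = p_genuine,

mapping the true prevalence ``pi`` of the sensitive trait to the observed
"yes" probability ``lambda``.  Inverting this line is what makes
population-level estimation possible even though no individual answer is
informative on its own.

Direct questioning is the degenerate member of the family with
``(c, d) = (0, 1)``, which lets the same estimation and regression code
handle both survey arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeckSpec",
    "RRDesign",
    "InvalidDesignError",
    "design_from_deck",
    "direct_design",
    "response_probability",
    "randomize_response",
    "SPANISH_DECK",
    "STUDY_DESIGN",
]

_PROB_TOL = 1e-12


class InvalidDesignError(ValueError):
    """Raised for devices under which the prevalence estimator is undefined."""


@dataclass(frozen=True)
class DeckSpec:
    """A physical card deck used as the randomizing device.

    Cards are partitioned into forced-"yes" cards, forced-"no" cards and
    cards that request the genuine answer.  At least one genuine card is
    required, otherwise the observed answers carry no information about
    the sensitive trait.
    """

    total_cards: int
    forced_yes_cards: int
    forced_no_cards: int
    genuine_cards: int

    def __post_init__(self) -> None:
        counts = (self.forced_yes_cards, self.forced_no_cards, self.genuine_cards)
        if self.total_cards <= 0:
            raise ValueError("total_cards must be a positive integer")
        if any(k < 0 for k in counts):
            raise ValueError("card counts must be non-negative")
        if sum(counts) != self.total_cards:
            raise ValueError(
                f"card counts {counts} do not sum to total_cards={self.total_cards}"
            )
        if self.genuine_cards < 1:
            raise InvalidDesignError(
                "a deck needs at least one genuine-answer card; with none, "
                "the prevalence estimator is undefined"
            )


@dataclass(frozen=True)
class RRDesign:
    """A forced-response design as a probability triple.

    Attributes
    ----------
    p_forced_yes, p_forced_no, p_genuine
        Device outcome probabilities; must sum to one and ``p_genuine``
        must be strictly positive.
    """

    p_forced_yes: float
    p_forced_no: float
    p_genuine: float

    def __post_init__(self) -> None:
        probs = (self.p_forced_yes, self.p_forced_no, self.p_genuine)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"design probabilities must lie in [0, 1], got {probs}")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ValueError(f"design probabilities must sum to 1, got {probs}")
        if self.p_genuine <= 0:
            raise InvalidDesignError(
                "p_genuine must be > 0; a device that never requests the "
                "genuine answer admits no prevalence estimator"
            )

    @property
    def c(self) -> float:
        """Misclassification intercept: P(observed yes | true status 0)."""
        return self.p_forced_yes

    @property
    def d(self) -> float:
        """Misclassification slope: probability of a genuine answer."""
        return self.p_genuine

    @property
    def is_direct(self) -> bool:
        return self.p_forced_yes == 0.0 and self.p_forced_no == 0.0


def design_from_deck(deck: DeckSpec) -> RRDesign:
    """Derive device probabilities from a card deck.

    Probabilities are exact card-count fractions, so decks that differ
    only in which card identities carry which instruction yield identical
    designs.
    """
    t = deck.total_cards
    return RRDesign(
        p_forced_yes=deck.forced_yes_cards / t,
        p_forced_no=deck.forced_no_cards / t,
        p_genuine=deck.genuine_cards / t,
    )


def direct_design() -> RRDesign:
    """The degenerate design representing direct questioning: (c, d) = (0, 1)."""
    return RRDesign(0.0, 0.0, 1.0)


def response_probability(design: RRDesign, true_prevalence):
    """Observed "yes" probability ``lambda = c + d * pi``.

    Accepts a scalar or array of true prevalences in [0, 1]; the result is
    confined to the identifiable band ``[c, c + d]``.
    """
    pi = np.asarray(true_prevalence, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("true_prevalence must lie in [0, 1]")
    lam = design.c + design.d * pi
    return float(lam) if np.isscalar(true_prevalence) else lam


def randomize_response(true_status, design: RRDesign, rng: np.random.Generator):
    """Draw observed answers for true statuses through the device.

    Card draws are independent with replacement (the card is returned to
    the deck after each question), so each answer is Bernoulli with
    success probability ``c + d * true_status``.

    Parameters
    ----------
    true_status : int or array of {0, 1}
    design : RRDesign
    rng : numpy Generator (explicit stream; identical streams reproduce
        identical draws)
    """
    status = np.asarray(true_status)
    if not np.isin(status, (0, 1)).all():
        raise ValueError("true_status must be binary (0/1)")
    p_yes = design.c + design.d * status
    draws = (rng.random(status.shape) < p_yes).astype(np.int8)
    return int(draws) if np.isscalar(true_status) or status.shape == () else draws


#: The 40-card Spanish-format deck used in the prison survey: numbers 1-2
#: of each of four suits force a "yes" (8 cards), 3-4 force a "no"
#: (8 cards), and 5-7 plus the three figures request the genuine answer
#: (24 cards).
SPANISH_DECK = DeckSpec(
    total_cards=40, forced_yes_cards=8, forced_no_cards=8, genuine_cards=24
)

#: Design derived from SPANISH_DECK: (p1, p2, p3) = (0.2, 0.2, 0.6),
#: misclassification line (c, d) = (0.2, 0.6).
STUDY_DESIGN = design_from_deck(SPANISH_DECK)
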