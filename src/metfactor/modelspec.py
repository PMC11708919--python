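"""Model-spec grammar naming which EC terms train the loading prior and which
predict new environments.

A spec string reads ``<prior>::<predictor>``, each side a ``+``-joined list of
EC term names or the letter ``O``.  The prior side always contains the
intercept; ``O`` there means intercept-only.  ``O`` on the predictor side is
the sentinel CONSTANT: new-environment predictions fall back to averaging
per-experiment predictions (a constant per genotype) rather than using Eq-style
loading regression.

Examples: ``S+T::S+T`` trains the loading prior on State and Tester and uses
both to predict; ``S+T::T`` trains on both but predicts with Tester only;
``O::O`` is the intercept-only model with constant prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data import INTERCEPT

CONSTANT = "CONSTANT"


class ModelSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    prior_terms: tuple[str, ...]      # named terms, intercept implicit+included
    predictor_terms: tuple[str, ...] | str  # tuple of names, or CONSTANT
    label: str

    @property
    def uses_constant(self) -> bool:
        return self.predictor_terms == CONSTANT

    @property
    def n_predictor_terms(self) -> int:
        return 0 if self.uses_constant else len(self.predictor_terms)


def _parse_side(side: str, known: list[str], what: str) -> tuple[str, ...] | None:
    side = side.strip()
    if not side:
        raise ModelSpecError(f"empty {what} side in model spec")
    if side == "O":
        return None
    names = [s.strip() for s in side.split("+")]
    if any(not s for s in names):
        raise ModelSpecError(f"malformed {what} side: {side!r}")
    unknown = [s for s in names if s not in known]
    if unknown:
        raise ModelSpecError(f"unknown EC term name(s) {unknown} on {what} side; "
                             f"known terms: {sorted(known)}")
    if len(set(names)) != len(names):
        raise ModelSpecError(f"duplicate term on {what} side: {side!r}")
    # normalize to known-term order
    return tuple(n for n in known if n in set(names))


def parse_model_spec(spec: str, known_terms) -> ModelSpec:
    """Parse ``"A+B::C"`` against the known EC term names.

    Raises :class:`ModelSpecError` on malformed strings or unknown names.
    """
    known = [t for t in known_terms if t != INTERCEPT]
    parts = spec.split("::")
    if len(parts) != 2:
        raise ModelSpecError(f"model spec must contain exactly one '::': {spec!r}")
    prior = _parse_side(parts[0], known, "prior")
    pred = _parse_side(parts[1], known, "predictor")
    prior_terms = prior or ()
    if pred is None:
        predictor_terms: tuple[str, ...] | str = CONSTANT
    else:
        extra = [p for p in pred if p not in set(prior_terms)]
        if extra:
            raise ModelSpecError(
                f"predictor term(s) {extra} not in the prior side of {spec!r}")
        predictor_terms = pred
    return ModelSpec(prior_terms, predictor_terms, _label(prior_terms, predictor_terms))


def _label(prior_terms, predictor_terms) -> str:
    left = "+".join(prior_terms) if prior_terms else "O"
    right = "O" if predictor_terms == CONSTANT else "+".join(predictor_terms)
    return f"{left}::{right}"
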