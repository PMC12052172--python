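"""Comparing reconstructed calls against planted ground truth.

A call matches a truth circle when, after canonical rotation, the two
fragment lists agree chromosome-for-chromosome with every boundary
within a tolerance.  Matching is one-to-one and greedy in call order.
"""
from __future__ import annotations

from dataclasses import dataclass

from .calling import _canonical_rotation

__all__ = ["evaluate_calls", "circles_match", "EvaluationResult"]


def circles_match(
    frags_a: list[tuple[str, int, int, str]],
    frags_b: list[tuple[str, int, int, str]],
    tolerance: int = 0,
) -> bool:
    """Do two circles describe the same structure within ``tolerance`` bp?"""
    a = _canonical_rotation(list(frags_a))
    b = _canonical_rotation(list(frags_b))
    if len(a) != len(b):
        return False
    return all(
        ca == cb
        and sa_strand == sb_strand
        and abs(sa - s2) <= tolerance
        and abs(ea - e2) <= tolerance
        for (ca, sa, ea, sa_strand), (cb, s2, e2, sb_strand) in zip(a, b)
    )


@dataclass
class EvaluationResult:
    n_truth: int
    n_calls: int
    n_matched: int
    boundary_exact: int  # matched pairs with every boundary exactly equal
    form_correct: int  # matched pairs with equal simple/complex labels
    matches: list[tuple[str, str]]  # (ecc_id, circle_id)

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_calls if self.n_calls else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def evaluate_calls(calls, truth_circles, tolerance: int = 0) -> EvaluationResult:
    """Greedy one-to-one matching of calls to truth circles."""
    unmatched = list(truth_circles)
    matches = []
    boundary_exact = 0
    form_correct = 0
    for call in calls:
        for t in unmatched:
            if circles_match(call.fragments, t.fragments, tolerance):
                matches.append((call.ecc_id, t.circle_id))
                if circles_match(call.fragments, t.fragments, 0):
                    boundary_exact += 1
                if call.form == t.form:
                    form_correct += 1
                unmatched.remove(t)
                break
    return EvaluationResult(
        n_truth=len(list(truth_circles)),
        n_calls=len(list(calls)),
        n_matched=len(matches),
        boundary_exact=boundary_exact,
        form_correct=form_correct,
        matches=matches,
    )
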