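"""AIC-based backward elimination of model terms, respecting marginality."""

from __future__ import annotations

from typing import Callable, Sequence


def term_factors(term: str) -> frozenset:
    """The set of factors a (patsy-style) interaction term is built from."""
    return frozenset(p.strip() for p in term.split(":"))


def _droppable(terms: Sequence[str], keep: Sequence[str]) -> list[str]:
    """Terms whose removal respects marginality: a term may be dropped only
    while no retained term's factor set strictly contains its own."""
    out = []
    for t in terms:
        if t in keep:
            continue
        fs = term_factors(t)
        if any(fs < term_factors(o) for o in terms if o != t):
            continue
        out.append(t)
    return out


def backward_eliminate(
    terms: Sequence[str],
    fit: Callable[[list[str]], object],
    keep: Sequence[str] = (),
    tol: float = 1e-9,
) -> tuple[list[str], object]:
    """Repeatedly drop the term whose removal lowers AIC most.

    ``fit`` maps a term list to a fitted result exposing ``.aic``.  Main
    effects are retained while any of their interactions remain; ties in
    AIC are broken by dropping the higher-order term first.  Stops when no
    allowed drop lowers AIC; returns (retained terms, fitted result).
    """
    current = list(terms)
    best = fit(current)
    while True:
        candidates = []
        for t in _droppable(current, keep):
            reduced = [x for x in current if x != t]
            res = fit(reduced)
            # sort key: AIC, then prefer dropping higher-order terms
            candidates.append((res.aic, -len(term_factors(t)), t, res))
        if not candidates:
            return current, best
        candidates.sort(key=lambda c: (c[0], c[1]))
        aic, _, t, res = candidates[0]
        if aic < best.aic - tol:
            current = [x for x in current if x != t]
            best = res
        else:
            return current, best
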