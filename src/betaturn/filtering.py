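"""State-flipping filters enforcing at least four-residue predicted turns.

Residue-level classification can emit turn runs shorter than the four
residues a beta-turn occupies.  Four rewrite rules, applied in a fixed
order, clean these up: (1) tnt -> ttt, (2) ntn -> nnn, (3) nttn -> nnnn,
(4) ntttn -> ttttt.  Each rule is a single simultaneous-match pass over
the string: matches are located on the pre-pass string and all flips
applied together, so the outcome does not depend on scan direction.
Both ends of the chain behave as virtual non-turn ('n') context; rule 4
can only flip positions that actually exist in the chain, so a terminal
three-run extends inward only.

The four-rule cycle is repeated until the string stops changing: a
later rule can create a context for an earlier one (rule 4 extending a
three-run can leave a single-gap ``tnt`` for rule 1), and filtering must
be idempotent — re-filtering an already filtered prediction changes
nothing.  Convergence is fast: after one cycle every turn run is at
least three residues long, so at most a few cycles are ever needed.
"""

from __future__ import annotations

__all__ = ["filter_channel", "filter_all"]

_ALPHABET = frozenset("tn")


def _check(s: str) -> None:
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"prediction string contains invalid symbols: {sorted(bad)}")


def _at(s: str, i: int) -> str:
    """Character at i with virtual 'n' padding beyond both termini."""
    return s[i] if 0 <= i < len(s) else "n"


def filter_channel(s: str) -> str:
    """Apply the ordered state-flipping rules until a fixpoint is reached."""
    _check(s)
    prev = None
    # each cycle strictly resolves short runs; the bound is a safeguard
    for _ in range(len(s) + 1):
        if s == prev:
            return s
        prev = s
        s = _one_cycle(s)
    return s


def _one_cycle(s: str) -> str:
    """One ordered application of the four rules, each a single
    simultaneous-match pass."""
    L = len(s)

    # rule 1: isolated non-turn between turns becomes turn (tnt -> ttt)
    cur = list(s)
    for i in range(L):
        if s[i] == "n" and _at(s, i - 1) == "t" and _at(s, i + 1) == "t":
            cur[i] = "t"
    s = "".join(cur)

    # rule 2: isolated single turn becomes non-turn (ntn -> nnn)
    cur = list(s)
    for i in range(L):
        if s[i] == "t" and _at(s, i - 1) == "n" and _at(s, i + 1) == "n":
            cur[i] = "n"
    s = "".join(cur)

    # rule 3: isolated turn pair becomes non-turn (nttn -> nnnn)
    cur = list(s)
    for i in range(L - 1):
        if (s[i] == "t" and s[i + 1] == "t"
                and _at(s, i - 1) == "n" and _at(s, i + 2) == "n"):
            cur[i] = cur[i + 1] = "n"
    s = "".join(cur)

    # rule 4: isolated turn triple absorbs its in-chain neighbours
    # (ntttn -> ttttt); virtual positions beyond the termini cannot flip
    cur = list(s)
    for i in range(L - 2):
        if (s[i] == s[i + 1] == s[i + 2] == "t"
                and _at(s, i - 1) == "n" and _at(s, i + 3) == "n"):
            if i - 1 >= 0:
                cur[i - 1] = "t"
            if i + 3 < L:
                cur[i + 3] = "t"
    return "".join(cur)


def filter_all(channels: dict[str, str]) -> dict[str, str]:
    """Filter each of the six prediction channels independently."""
    lengths = {len(v) for v in channels.values()}
    if len(lengths) > 1:
        raise ValueError("prediction channels have unequal lengths")
    return {name: filter_channel(s) for name, s in channels.items()}
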