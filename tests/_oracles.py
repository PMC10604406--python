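"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible — nested loops, no
shared helpers with the package — so a bug in the implementation cannot
hide in the oracle.
"""

from __future__ import annotations

import re


def oracle_tokens(text: str) -> list[str]:
    return re.findall(r"[^\W_]+", text.lower(), flags=re.UNICODE)


def _phrase_positions(tokens, phrase_tokens):
    hits = []
    n = len(phrase_tokens)
    for i in range(len(tokens) - n + 1):
        if tokens[i : i + n] == phrase_tokens:
            hits.append((i, i + n - 1))
    return hits


def oracle_keyword_counts(text, entries, pre_triggers, post_triggers, terminators,
                          proximity_window=5, scope=5):
    """Non-negated keyword counts for one note.

    ``entries`` is a list of dicts with keys canonical, variants,
    requires_proximity, location_terms.
    """
    tokens = oracle_tokens(text)

    # negated token positions, recomputed from scratch
    negated = set()
    for trig in pre_triggers:
        for (_, e) in _phrase_positions(tokens, trig.lower().split()):
            j = e + 1
            while j < len(tokens) and j <= e + scope:
                if tokens[j] in terminators:
                    break
                negated.add(j)
                j += 1
    for trig in post_triggers:
        for (s, _) in _phrase_positions(tokens, trig.lower().split()):
            j = s - 1
            while j >= 0 and j >= s - scope:
                if tokens[j] in terminators:
                    break
                negated.add(j)
                j -= 1

    counts = {}
    for entry in entries:
        starts = set()
        for variant in entry["variants"]:
            for (s, e) in _phrase_positions(tokens, variant.lower().split()):
                if entry.get("requires_proximity"):
                    near = False
                    for loc in entry["location_terms"]:
                        for (ls, le) in _phrase_positions(tokens, loc.lower().split()):
                            dist = ls - e if ls > e else s - le
                            if dist <= proximity_window:
                                near = True
                    if not near:
                        continue
                # variants of one keyword starting at the same position count once
                starts.add(s)
        n = 0
        for s in starts:
            if s not in negated:
                n += 1
        counts[entry["canonical"]] = n
    return counts


def oracle_consecutive_antibiotic_days(day_list, lo=2, hi=45, run=3):
    """True iff some window of `run` consecutive days in [lo, hi] is covered."""
    days = set(d for d in day_list if lo <= d <= hi)
    for start in range(lo, hi - run + 2):
        if all(start + k in days for k in range(run)):
            return True
    return False


def oracle_quartiles(values):
    """Q1/Q3 by linear interpolation on the sorted sample (manual)."""
    xs = sorted(values)
    n = len(xs)

    def q(p):
        h = p * (n - 1)
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.75)


def oracle_bin(count, q1, q3):
    if count == 0:
        return "none"
    if count < q1:
        return "below"
    if count <= q3:
        return "within"
    return "above"
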