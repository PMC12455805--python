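"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written against the *stated definitions*
(string splitting, exhaustive enumeration, quadratic scans) rather than
reusing any code path from the package.
"""

from __future__ import annotations

from itertools import product
from math import comb


# ---------------------------------------------------------------------------
# module-definition expansion by recursive string splitting
# ---------------------------------------------------------------------------


def _split_top(s: str, seps: set[str]) -> list[str]:
    """Split on top-level separator characters (paren depth 0)."""
    parts, depth, start = [], 0, 0
    for i, c in enumerate(s):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif depth == 0 and c in seps:
            # '--' is a token, not two separators
            if c == "-" and (s[i : i + 2] == "--" or s[i - 1 : i + 1] == "--"):
                continue
            parts.append(s[start:i])
            start = i + 1
    parts.append(s[start:])
    return parts


def expand_definition(defstr: str) -> set[frozenset[str]]:
    """All distinct KO sets realizing every step one way (exhaustive).

    Top-level spaces are AND, commas OR, '+' complex AND, '-' optional
    (contributes nothing), '--' a gap satisfied by anything.
    """
    s = defstr.strip()
    and_parts = [p for p in _split_top(s, {" "}) if p.strip()]
    if len(and_parts) > 1:
        combos = {frozenset()}
        for part in and_parts:
            combos = {
                a | b for a in combos for b in expand_definition(part)
            }
        return combos
    s = and_parts[0].strip()
    or_parts = _split_top(s, {","})
    if len(or_parts) > 1:
        out: set[frozenset[str]] = set()
        for part in or_parts:
            out |= expand_definition(part)
        return out
    s = or_parts[0].strip()
    if s == "--":
        return {frozenset()}
    if s.startswith("(") and s.endswith(")") and _balanced_wrap(s):
        return expand_definition(s[1:-1])
    # complex: split on +/-, members after '-' are optional
    plus_minus = _split_complex(s)
    if len(plus_minus) > 1:
        combos = {frozenset()}
        for member, optional in plus_minus:
            opts = (
                {frozenset()} if optional else expand_definition(member)
            )
            combos = {a | b for a in combos for b in opts}
        return combos
    return {frozenset({s})}


def _balanced_wrap(s: str) -> bool:
    depth = 0
    for i, c in enumerate(s):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth == 0 and i < len(s) - 1:
                return False
    return True


def _split_complex(s: str) -> list[tuple[str, bool]]:
    out: list[tuple[str, bool]] = []
    depth, start, optional = 0, 0, False
    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif depth == 0 and c in "+-":
            if c == "-" and s[i : i + 2] == "--" and start == i:
                i += 2
                continue
            if i > start:
                out.append((s[start:i], optional))
            optional = c == "-"
            start = i + 1
        i += 1
    out.append((s[start:], optional))
    return [(m, o) for m, o in out if m]


# ---------------------------------------------------------------------------
# complement search by direct set conditions
# ---------------------------------------------------------------------------


def complements_oracle(
    beneficiary_kos: frozenset[str],
    donor_kos: frozenset[str],
    alternatives_by_module: dict[str, list[frozenset[str]]],
    max_missing: int | None = None,
) -> set[tuple[str, frozenset[str]]]:
    """(module, missing set) pairs satisfying the three set conditions."""
    out: set[tuple[str, frozenset[str]]] = set()
    for module_id, alts in alternatives_by_module.items():
        if any(a <= beneficiary_kos for a in alts):
            continue
        for a in alts:
            missing = a - beneficiary_kos
            if not missing or not missing <= donor_kos:
                continue
            if max_missing is not None and len(missing) > max_missing:
                continue
            out.add((module_id, missing))
    return out


def unique_pairs_oracle(records: list[tuple[str, frozenset[str]]]) -> int:
    """Count distinct (module, missing) pairs by naive pairwise comparison."""
    uniques: list[tuple[str, frozenset[str]]] = []
    for rec in records:
        if not any(rec[0] == u[0] and rec[1] == u[1] for u in uniques):
            uniques.append(rec)
    return len(uniques)


# ---------------------------------------------------------------------------
# graph oracles
# ---------------------------------------------------------------------------


def edge_set_oracle(reactions) -> set[tuple[str, str]]:
    """Substrate→product edges derived reaction by reaction."""
    edges: set[tuple[str, str]] = set()
    for rxn in reactions:
        for s in rxn.substrates:
            for p in rxn.products:
                if s == p:
                    continue
                edges.add((s, p))
                if rxn.reversible:
                    edges.add((p, s))
    return edges


def reachable_from(adj: dict[str, set[str]], start: str) -> set[str]:
    seen = {start}
    stack = [start]
    while stack:
        for nxt in adj.get(stack.pop(), ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def scc_partition_oracle(nodes, edges) -> dict[str, int]:
    """SCCs by O(n^2) mutual reachability; ids are arbitrary but consistent."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
    reach = {n: reachable_from(adj, n) for n in nodes}
    scc_of: dict[str, int] = {}
    next_id = 0
    for n in nodes:
        if n in scc_of:
            continue
        for m in nodes:
            if m in reach[n] and n in reach[m]:
                scc_of[m] = next_id
        next_id += 1
    return scc_of


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------


def levenshtein_dp(a: str, b: str) -> int:
    """Plain dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by exhaustive combinatorial summation."""
    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
    ) / total


def hypergeom_lower_tail(k: int, N: int, K: int, n: int) -> float:
    total = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(0, min(k, K, n) + 1)
        if n - x <= N - K
    ) / total


def bh_stepup(p_values: list[float]) -> list[float]:
    """BH q-values evaluated directly from the step-up formula."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = min(running, 1.0)
    return q
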