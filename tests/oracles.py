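"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive — direct rule application, exhaustive
dynamic programming, grid scans — and shares no code with the implementation
paths it verifies.
"""

from __future__ import annotations

import itertools


# ---------------------------------------------------------------------------
# tier assignment: direct application of the confidence-tier rules to a
# peptide -> claimant-groups incidence map

def oracle_tiers(
    claimants: dict[str, frozenset[int]],
    groups: list[int],
    core_groups: set[int],
    accession_of: dict[int, str],
) -> dict[int, str]:
    observed = {
        g: {p for p, cl in claimants.items() if g in cl} for g in groups
    }
    unique = {
        g: sum(1 for cl in claimants.values() if cl == frozenset([g]))
        for g in groups
    }
    canonical = {g for g in groups if unique[g] >= 2}

    # identical observed peptide sets: promote one member when >=2 peptides
    # are confined to the tie class
    seen_sets: dict[frozenset[str], list[int]] = {}
    for g in groups:
        if observed[g] and g not in canonical:
            seen_sets.setdefault(frozenset(observed[g]), []).append(g)
    for peps, members in seen_sets.items():
        if len(members) < 2:
            continue
        confined = [p for p in peps if set(claimants[p]) <= set(members)]
        if len(confined) < 2:
            continue
        in_core = [m for m in members if m in core_groups]
        pool = in_core or members
        canonical.add(min(pool, key=lambda m: (accession_of[m], m)))

    result: dict[int, str] = {}
    for g in groups:
        if not observed[g]:
            result[g] = "not_observed"
        elif g in canonical:
            result[g] = "canonical"
        elif unique[g] == 1 and any(set(claimants[p]) & canonical for p in observed[g]):
            result[g] = "marginal"
        elif unique[g] == 0 and all(set(claimants[p]) & canonical for p in observed[g]):
            result[g] = "indistinguishable"
        else:
            result[g] = "uncertain"
    return result


# ---------------------------------------------------------------------------
# pairwise identity: full Gotoh affine-gap dynamic programming

def oracle_identity(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                    gap_open: float = -5.0, gap_extend: float = -1.0) -> float:
    """Global affine-gap alignment identity over the shorter sequence.

    Three-state Gotoh DP augmented with the maximum identity count achievable
    among score-optimal alignments reaching each cell; gap_open is the score
    of a gap's first residue.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    # per state: (best score, max identities among paths with that score)
    M = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        X[i][0] = (gap_open + gap_extend * (i - 1), 0)
    for j in range(1, m + 1):
        Y[0][j] = (gap_open + gap_extend * (j - 1), 0)

    def best(cands):
        top = max(s for s, _ in cands)
        if top == NEG:
            return (NEG, 0)
        return (top, max(ident for s, ident in cands if s == top))

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            is_match = a[i - 1] == b[j - 1]
            s = match if is_match else mismatch
            diag = best([M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]])
            M[i][j] = (diag[0] + s, diag[1] + (1 if is_match else 0))
            X[i][j] = best([
                (M[i - 1][j][0] + gap_open, M[i - 1][j][1]),
                (X[i - 1][j][0] + gap_extend, X[i - 1][j][1]),
                (Y[i - 1][j][0] + gap_open, Y[i - 1][j][1]),
            ])
            Y[i][j] = best([
                (M[i][j - 1][0] + gap_open, M[i][j - 1][1]),
                (Y[i][j - 1][0] + gap_extend, Y[i][j - 1][1]),
                (X[i][j - 1][0] + gap_open, X[i][j - 1][1]),
            ])
    _score, identities = best([M[n][m], X[n][m], Y[n][m]])
    return identities / min(n, m)


def oracle_best_score(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                      gap_open: float = -5.0, gap_extend: float = -1.0) -> float:
    """Optimal global affine-gap alignment score (no traceback)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# ---------------------------------------------------------------------------
# naive tryptic digestion and detectable-peptide counting

def oracle_tryptic_peptides(sequence: str, missed_cleavages: int) -> list[tuple[str, int]]:
    """Cut after K/R not before P; return (peptide, 1-based start)."""
    cuts = [0]
    for i, res in enumerate(sequence):
        if res in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            cuts.append(i + 1)
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    segments = [
        (sequence[cuts[k]:cuts[k + 1]], cuts[k] + 1) for k in range(len(cuts) - 1)
    ]
    out = []
    for k in range(len(segments)):
        for mc in range(missed_cleavages + 1):
            if k + mc >= len(segments):
                break
            pep = "".join(seg for seg, _ in segments[k:k + mc + 1])
            out.append((pep, segments[k][1]))
    return out


def oracle_detectable_count(sequence: str, min_length: int,
                            mass_window: tuple[float, float],
                            mono_masses: dict[str, float],
                            water: float) -> int:
    lo, hi = mass_window
    n = 0
    for pep, _ in oracle_tryptic_peptides(sequence, 0):
        if len(pep) < min_length or "X" in pep:
            continue
        mass = water + sum(mono_masses[r] for r in pep)
        if lo <= mass <= hi:
            n += 1
    return n


# ---------------------------------------------------------------------------
# clustering: all-pairs assignment to representatives, longest-first

def oracle_greedy_clusters(sequences: dict[int, str],
                           identity_fn, threshold: float) -> list[list[int]]:
    """All-pairs re-derivation of representative-based greedy clustering."""
    order = sorted(sequences, key=lambda g: (-len(sequences[g]), g))
    reps: list[int] = []
    members: dict[int, list[int]] = {}
    for g in order:
        for rep in reps:
            if identity_fn(sequences[g], sequences[rep]) >= threshold:
                members[rep].append(g)
                break
        else:
            reps.append(g)
            members[g] = [g]
    return [members[r] for r in reps]


# ---------------------------------------------------------------------------
# isoelectric point: fine grid scan for the zero-charge pH

def oracle_pi_grid(net_charge_fn, sequence: str, step: float = 0.0001) -> float:
    best_ph, best_abs = 0.0, float("inf")
    ph = 0.0
    while ph <= 14.0:
        q = abs(net_charge_fn(sequence, ph))
        if q < best_abs:
            best_abs, best_ph = q, ph
        ph += step
    return best_ph


# ---------------------------------------------------------------------------
# enumeration of peptide -> group incidence structures

def enumerate_claimant_maps(n_groups: int, n_peptides: int):
    """Yield every assignment of each peptide to a non-empty group subset."""
    subsets = [
        frozenset(c)
        for r in range(1, n_groups + 1)
        for c in itertools.combinations(range(n_groups), r)
    ]
    for combo in itertools.product(subsets, repeat=n_peptides):
        yield {f"PEP{i}": cl for i, cl in enumerate(combo)}
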