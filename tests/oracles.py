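"""Independent brute-force oracles for the game-theory predictors.

Deliberately written with plain Python loops over the 9 outcome cells and
all unilateral deviations — no shared code with the package implementation.
"""

ACTIONS_ROW = ("Top", "Middle", "Bottom")
ACTIONS_COL = ("Left", "Middle", "Right")


def nash_oracle(row_payoffs, col_payoffs):
    """All strict pure Nash cells, by testing every unilateral deviation."""
    cells = set()
    for r in range(3):
        for c in range(3):
            ok = True
            for q in range(3):
                if q != r and row_payoffs[q][c] >= row_payoffs[r][c]:
                    ok = False
            for q in range(3):
                if q != c and col_payoffs[r][q] >= col_payoffs[r][c]:
                    ok = False
            if ok:
                cells.add((ACTIONS_ROW[r], ACTIONS_COL[c]))
    return cells


def dominant_oracle_row(row_payoffs):
    """Strictly dominant row action by pairwise comparison, or None."""
    for a in range(3):
        dominates_all = True
        for b in range(3):
            if b == a:
                continue
            if not all(row_payoffs[a][c] > row_payoffs[b][c] for c in range(3)):
                dominates_all = False
        if dominates_all:
            return ACTIONS_ROW[a]
    return None


def dominant_oracle_col(col_payoffs):
    for a in range(3):
        dominates_all = True
        for b in range(3):
            if b == a:
                continue
            if not all(col_payoffs[r][a] > col_payoffs[r][b] for r in range(3)):
                dominates_all = False
        if dominates_all:
            return ACTIONS_COL[a]
    return None


def naive_oracle(row_payoffs):
    """Row with the strictly highest average payoff, or None on a tie."""
    means = [sum(row_payoffs[r]) / 3.0 for r in range(3)]
    best = max(means)
    winners = [r for r in range(3) if means[r] == best]
    return ACTIONS_ROW[winners[0]] if len(winners) == 1 else None


def coordination_oracle(row_payoffs, col_payoffs):
    """Exhaustive two-key sort over the 9 cells: max sum, then min |diff|.

    Returns the winning row action, or None if the two keys leave a tie.
    """
    scored = []
    for r in range(3):
        for c in range(3):
            s = row_payoffs[r][c] + col_payoffs[r][c]
            d = abs(row_payoffs[r][c] - col_payoffs[r][c])
            scored.append((-s, d, r, c))
    scored.sort()
    if scored[0][:2] == scored[1][:2]:
        return None
    return ACTIONS_ROW[scored[0][2]]
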