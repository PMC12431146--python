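"""Independent brute-force oracles used by unit and acceptance tests.

Each function recomputes a quantity by a different route than the package
implementation: exact integration of the linear interpolant on a knot-
containing grid, 1-second interval counting, and plain loops over
definitions.
"""

import numpy as np


def auc_oracle(hours, glucose, lo, hi, n_fine=100_001):
    """Integral of the linear interpolant of (hours, glucose) over [lo, hi].

    Trapezoid over the union of a fine uniform grid and the knots: exact
    for a piecewise-linear function because every knot is a grid point.
    """
    hours = np.asarray(hours, dtype=float)
    grid = np.union1d(np.linspace(lo, hi, n_fine), hours[(hours >= lo) & (hours <= hi)])
    grid = grid[(grid >= lo) & (grid <= hi)]
    vals = np.interp(grid, hours, glucose)
    return float(np.trapezoid(vals, grid))


def iauc_oracle(hours, glucose, lo, hi, n_fine=300_001):
    """Integral of max(interpolant - interpolant(lo), 0) over [lo, hi].

    Baseline crossings are not grid knots, so this is a dense-grid
    approximation, accurate to ~1e-7 relative at the default resolution.
    """
    hours = np.asarray(hours, dtype=float)
    grid = np.union1d(np.linspace(lo, hi, n_fine), hours[(hours >= lo) & (hours <= hi)])
    grid = grid[(grid >= lo) & (grid <= hi)]
    baseline = np.interp(lo, hours, glucose)
    vals = np.clip(np.interp(grid, hours, glucose) - baseline, 0.0, None)
    return float(np.trapezoid(vals, grid))


def durations_oracle(events, window_start_s, window_end_s, class_map):
    """Per-class seconds by counting every whole second in the window.

    ``events`` are (start_s, duration_s, activity) tuples in epoch seconds.
    """
    totals = {"sitting": 0, "standing": 0, "stepping": 0}
    for start, duration, activity in events:
        cls = class_map[activity]
        for s in range(int(start), int(start + duration)):
            if window_start_s <= s < window_end_s:
                totals[cls] += 1
    return totals


def soft_vote_oracle(member_probas):
    """Plain-loop average of per-member class-probability matrices."""
    n, k = member_probas[0].shape
    out = np.zeros((n, k))
    for p in member_probas:
        for i in range(n):
            for j in range(k):
                out[i, j] += p[i, j]
    return out / len(member_probas)


def cf_metrics_oracle(cf_matrix, query_vec, mu, sd, flipped, tol=1e-6):
    """Loop-based recomputation of the counterfactual set metrics."""
    Z = (cf_matrix - mu) / sd
    z0 = (query_vec - mu) / sd
    n = len(cf_matrix)
    validity = sum(bool(f) for f in flipped) / n
    pair_dists = []
    for i in range(n):
        for j in range(i + 1, n):
            pair_dists.append(np.abs(Z[i] - Z[j]).sum())
    diversity = float(np.mean(pair_dists)) if pair_dists else 0.0
    distance = float(np.mean([np.abs(z - z0).sum() for z in Z]))
    changed = float(np.mean([
        sum(abs(a - b) > tol for a, b in zip(row, query_vec)) for row in cf_matrix
    ]))
    return {"validity": validity, "diversity": diversity,
            "normalized_distance": distance, "features_changed": changed}
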