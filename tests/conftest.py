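import numpy as np
import pytest

from crpmr.datamodel import load_table1_fixture
from crpmr.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def big_cohort():
    """One large exposure-scale cohort (n=50,000) shared by the GWAS tests."""
    return simulate_cohort(SimConfig(n_subjects=50_000, seed=123))


def brute_force_lin_ying(time, event, Z):
    """Independent oracle for the constant-effect additive-hazards estimator.

    Enumerates the distinct observed times and computes the risk-set
    integrals A, b and the event-sum B by explicit nested summation, straight
    from their definitions.  O(n * m * p^2); only for tiny instances.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    Z = np.asarray(Z, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n, p = Z.shape
    grid = np.unique(time)
    A = np.zeros((p, p))
    b = np.zeros(p)
    B = np.zeros((p, p))
    prev = 0.0
    for tk in grid:
        at_risk = time >= tk
        zbar = Z[at_risk].mean(axis=0)
        dt = tk - prev
        for i in np.where(at_risk)[0]:
            d = Z[i] - zbar
            A += dt * np.outer(d, d)
        for i in np.where((time == tk) & (event > 0))[0]:
            d = Z[i] - zbar
            b += d
            B += np.outer(d, d)
        prev = tk
    beta = np.linalg.solve(A, b)
    Ainv = np.linalg.inv(A)
    return beta, Ainv @ B @ Ainv


def brute_force_clump(scan, genotypes, r2_threshold, window_kb):
    """Greedy clumping restated from the definition with plain loops."""
    rows = scan.to_dict("records")
    rows.sort(key=lambda r: (r["p"], r["chrom"], r["pos"]))
    kept = []
    for row in rows:
        ok = True
        for acc in kept:
            if acc["chrom"] != row["chrom"]:
                continue
            if abs(acc["pos"] - row["pos"]) > window_kb * 1000:
                continue
            g1 = np.asarray(genotypes[row["id"]], float)
            g2 = np.asarray(genotypes[acc["id"]], float)
            r = np.corrcoef(g1, g2)[0, 1]
            if not np.isnan(r) and r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(row)
    return sorted(r["id"] for r in kept)
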