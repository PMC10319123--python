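import numpy as np
import pytest

from fixcca import CohortConfig, CovarianceTable, generate_cohort
from fixcca.congruency import pooled_covariances
from fixcca.epoching import concatenate_epochs, epoch_at_fixations
from fixcca.preprocessing import extract_condition_segments, load_fixations, preprocess_recording


SMALL_COHORT = dict(
    n_per_group=4,
    n_channels=12,
    n_conditions=2,
    letters_per_matrix=12,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-condition cohort reused across tests (read-only)."""
    cfg = CohortConfig(**SMALL_COHORT)
    recs, logs, manifest, truth = generate_cohort(cfg)
    return cfg, recs, logs, manifest, truth


def cohort_condition_table(recs, logs, condition, preprocess=True, shared_f=None):
    """Run preprocess -> segment -> align -> epoch -> concatenate for one
    condition and return (CovarianceTable, frp_sets, f_common)."""
    frps = []
    for rec, log in zip(recs, logs):
        windows = rec.condition_windows_ms()
        r = preprocess_recording(rec) if preprocess else rec
        segs = {s.condition: s for s in extract_condition_segments(r)}
        aligned = load_fixations(log, windows)
        fix = aligned[aligned["condition"] == condition]
        frps.append(epoch_at_fixations(segs[condition], fix))
    f_common = min(f.n_fixations for f in frps) if shared_f is None else shared_f
    mats = [concatenate_epochs(f, f_common) for f in frps]
    return CovarianceTable(mats), frps, f_common


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    """Covariance table for condition 1 of the small cohort."""
    cfg, recs, logs, manifest, truth = small_cohort
    table, frps, f_common = cohort_condition_table(recs, logs, condition=1)
    return table, frps, f_common, manifest, truth


def random_pencil(rng, d=4):
    """Random symmetric-PD (Rb, Rw) pair."""
    a = rng.standard_normal((d, d))
    rw = a @ a.T + d * np.eye(d)
    b = rng.standard_normal((d, 2 * d))
    rb = b @ b.T / (2 * d)
    return rb, rw


def pooled_from_mats(mats, shrinkage=0.0):
    return pooled_covariances(mats, shrinkage=shrinkage)
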