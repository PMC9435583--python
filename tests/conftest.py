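"""Shared fixtures: brute-force oracles and the planted/null cohort runs."""

from __future__ import annotations

import numpy as np
import pytest

from megfc.atlas import DEFAULT_DIFFERENTIAL_EDGE_LABELS, edges_from_labels
from megfc.features import edge_to_feature_index
from megfc.report_io import RunConfig, run_pipeline


def segment_count_bruteforce(block_duration_s, event_times_s, pad_s=10.0,
                             cut_len_s=10.0, min_keep_s=4.0) -> int:
    """Independent 1-ms-grid oracle for the exclude + partition count.

    Marks every millisecond of the block clean/dirty, finds maximal clean
    runs, and counts 10-s cuts (plus a trailing partial of >= 4 s) per run.
    Event times are expected on the millisecond grid.
    """
    n_ms = int(round(block_duration_s * 1000))
    clean = np.ones(n_ms, dtype=bool)
    for t in event_times_s:
        lo = max(0, int(round((t - pad_s) * 1000)))
        hi = min(n_ms, int(round((t + pad_s) * 1000)))
        clean[lo:hi] = False
    cut_ms = int(round(cut_len_s * 1000))
    keep_ms = int(round(min_keep_s * 1000))
    count = 0
    run = 0
    for bit in np.append(clean, False):
        if bit:
            run += 1
        elif run:
            count += run // cut_ms + (1 if run % cut_ms >= keep_ms else 0)
            run = 0
    return count


@pytest.fixture(scope="session")
def count_oracle():
    return segment_count_bruteforce


def brute_force_f_score(X, y, positive_label=1):
    """Two-pass scalar-loop evaluation of the per-feature F-score."""
    X = np.asarray(X, dtype=float)
    out = np.zeros(X.shape[1])
    pos = [k for k in range(len(y)) if y[k] == positive_label]
    neg = [k for k in range(len(y)) if y[k] != positive_label]
    for i in range(X.shape[1]):
        xb = sum(X[k, i] for k in range(len(y))) / len(y)
        xp = sum(X[k, i] for k in pos) / len(pos)
        xn = sum(X[k, i] for k in neg) / len(neg)
        sp = sum((X[k, i] - xp) ** 2 for k in pos) / (len(pos) - 1)
        sn = sum((X[k, i] - xn) ** 2 for k in neg) / (len(neg) - 1)
        num = (xn - xb) ** 2 + (xp - xb) ** 2
        den = sp + sn
        out[i] = num / den if den > 0 else 0.0
    return out


@pytest.fixture(scope="session")
def f_score_oracle():
    return brute_force_f_score


PLANTED_EDGES = edges_from_labels(DEFAULT_DIFFERENTIAL_EDGE_LABELS)


@pytest.fixture(scope="session")
def planted_edges():
    return PLANTED_EDGES


@pytest.fixture(scope="session")
def planted_feature_indices():
    return {edge_to_feature_index(i, j) for i, j in PLANTED_EDGES}


@pytest.fixture(scope="session")
def planted_run():
    """Full-scale planted cohort run: 16+16 subjects, 74 parcels, 5 edges
    (strength 0.6, lag 20 ms), ~60 segments/subject, both CV schemes."""
    cfg = RunConfig(n_subjects_per_group=16, n_parcels=74,
                    segments_per_subject_range=(40, 80),
                    edges=PLANTED_EDGES, strength=0.6, lag_ms=20.0, seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def null_runs():
    """20 seeded null cohorts (no group difference), subset scheme.

    Reduced per-subject segment yields keep 20 full pipeline runs
    tractable; chance level does not depend on the cohort size.
    """
    out = []
    for seed in range(20):
        cfg = RunConfig(n_subjects_per_group=16, n_parcels=74,
                        segments_per_subject_range=(8, 16),
                        edges=(), strength=0.0, seed=1000 + seed,
                        schemes=("subsets",))
        try:
            res = run_pipeline(cfg)
            m = res.metrics["schemes"]["subsets"]
            out.append((m["n_stable_features"], m["test_accuracy_pct"]))
        except ValueError:
            # empty stable set: no classifier can be finalized
            out.append((0, None))
    return out


@pytest.fixture(scope="session")
def small_run():
    """Fast reduced pipeline run for smoke/IO/determinism tests."""
    cfg = RunConfig(n_subjects_per_group=6, n_parcels=16,
                    segments_per_subject_range=(10, 16),
                    edges=((0, 5), (2, 9), (3, 12)), overlap_threshold=3,
                    n_reps=6, seed=7)
    return cfg, run_pipeline(cfg)
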