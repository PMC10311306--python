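"""Canonical evaluation designs on synthetic federations.

Each function builds one self-contained study on Balding–Nichols cohorts and
returns the quantity of interest: clustering accuracy against the
centralized benchmark without noise, membership-inference power of a
noise-free release, the elbow-selected cluster count across a privacy-budget
grid, and the empirical false-positive-rate calibration of the distance
attack. They are used by the reproduction script and the test suite; the
cohort sizes are chosen so every design runs in seconds to minutes on one
CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, qc_filter, restrict_to_snps
from .pca import fit_pca_model, researcher_payload
from .privacy import AttackConfig, AttackResult, calibrate_threshold, mi_power
from .privacy import _min_distances  # shared distance kernel
from .seeding import substream_seed
from .server import (
    aggregate_metadata,
    centralized_benchmark,
    score_accuracy,
    stratify,
)
from .simulate import SyntheticConfig, simulate_populations, split_federation


def _prepare(cohort, public, locals_):
    """Server-side QC fixes the agreed SNP list for every party."""
    public = qc_filter(public, maf_min=0.01, missing_max=0.05)
    locals_ = {r: restrict_to_snps(g, public.snp_ids) for r, g in locals_.items()}
    cohort = restrict_to_snps(cohort, public.snp_ids)
    return cohort, public, locals_


def no_noise_accuracy(seed: int, n_snps: int = 2000) -> float:
    """Accuracy of the noise-free federation versus the centralized benchmark.

    Five populations; researchers Ra/Rb hold 20 and 18 samples of
    populations P1 and P2; the server's public panel contains the remaining
    samples of all five populations, sized so each population keeps ~24
    panel samples after the researcher draws (a panel that under-represents
    the researchers' populations cannot span their separating direction
    with two components). The PCA model (d=2) is trained on the panel,
    both researchers share exact projections (no-noise sentinel), the
    server clusters with elbow-selected k, and the result is scored against
    PCA + k-means on the pooled raw data after Hungarian matching.
    """
    cfg = SyntheticConfig(5, [44, 43, 24, 24, 24], n_snps, 0.1,
                          seed=substream_seed(seed, "t1-sim"))
    cohort = simulate_populations(cfg)
    public, locals_ = split_federation(
        cohort, None,
        {"Ra": ["P1", "P2"], "Rb": ["P1", "P2"]},
        {"Ra": 20, "Rb": 18},
    )
    cohort, public, locals_ = _prepare(cohort, public, locals_)
    model = fit_pca_model(public, 2)
    payloads = [researcher_payload(model, locals_[r], math.inf) for r in ("Ra", "Rb")]
    report = stratify(aggregate_metadata(payloads), k="auto",
                      seed=substream_seed(seed, "t1-cluster"))
    bench = centralized_benchmark(
        [locals_["Ra"], locals_["Rb"]], public, 2, k="auto",
        seed=substream_seed(seed, "t1-bench"),
    )
    bench_by_id = dict(zip(bench.ids, bench.labels.tolist()))
    raw_ids = locals_["Ra"].sample_ids + locals_["Rb"].sample_ids
    bench_labels = np.array([bench_by_id[s] for s in raw_ids])
    return score_accuracy(report.labels, bench_labels)


def no_noise_attack(seed: int, n_snps: int = 800) -> AttackResult:
    """Euclidean-distance attack against a noise-free release.

    One researcher shares the exact projections of 100 members drawn from
    two of three populations; 100 disjoint controls come from the same two
    populations. Every member's minimum distance to the release is 0, so
    the attack's power at the 5%-FPR threshold is exactly 1.
    """
    cfg = SyntheticConfig(3, 100, n_snps, 0.1, seed=substream_seed(seed, "t2-sim"))
    cohort = simulate_populations(cfg)
    public, locals_ = split_federation(
        cohort, None, {"Ra": ["P1", "P2"]}, {"Ra": 100}
    )
    cohort, public, locals_ = _prepare(cohort, public, locals_)
    da = locals_["Ra"]
    model = fit_pca_model(public, 2)
    released = researcher_payload(model, da, math.inf)
    member_ids = set(da.sample_ids)
    lab = np.array(cohort.population_labels)
    pool = [
        i
        for i, s in enumerate(cohort.sample_ids)
        if s not in member_ids and lab[i] in ("P1", "P2")
    ]
    rng = np.random.default_rng(substream_seed(seed, "t2-controls"))
    controls = cohort.take_samples(sorted(rng.choice(pool, 100, replace=False).tolist()))
    return mi_power(AttackConfig(model, released, controls, da))


def elbow_selected_k(
    seed: int,
    n_replicates: int = 100,
    epsilons: tuple[float, ...] = (1.0, 3.0, 5.0),
    n_snps: int = 2000,
) -> list[tuple[float, int]]:
    """Elbow-selected cluster counts on a three-population federation.

    Per replicate: 3 populations of 50, researchers Ra (40 of P1/P2) and Rb
    (40 of P2/P3), public panel with all three; for each privacy budget the
    protocol runs with d=2 and the WCSS elbow scans k = 2..10. Returns one
    (epsilon, chosen_k) pair per replicate and budget.
    """
    out: list[tuple[float, int]] = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(3, 50, n_snps, 0.1,
                              seed=substream_seed(seed, "t3-sim", rep))
        cohort = simulate_populations(cfg)
        public, locals_ = split_federation(
            cohort, None,
            {"Ra": ["P1", "P2"], "Rb": ["P2", "P3"]},
            {"Ra": 40, "Rb": 40},
        )
        cohort, public, locals_ = _prepare(cohort, public, locals_)
        model = fit_pca_model(public, 2)
        for ei, eps in enumerate(epsilons):
            payloads = [
                researcher_payload(
                    model, locals_[r], eps,
                    rng_seed=substream_seed(seed, "t3-noise", rep, ei, r),
                )
                for r in ("Ra", "Rb")
            ]
            report = stratify(
                aggregate_metadata(payloads), k="auto", k_max=10,
                seed=substream_seed(seed, "t3-cluster", rep, ei),
            )
            out.append((eps, report.chosen_k))
    return out


@dataclass
class FprCalibration:
    threshold: float
    empirical_fpr_percent: float
    n_controls: int


def fpr_calibration(
    seed: int, epsilon: float = 3.0, n_controls: int = 1000, n_snps: int = 1000
) -> FprCalibration:
    """Held-out false-positive rate of the calibrated distance threshold.

    The release holds 100 members of two populations perturbed at the given
    budget; the threshold is calibrated on ``n_controls`` non-member
    distances and evaluated on an equally large fresh draw from the same
    non-member distribution. Returns the held-out FPR as a percentage.
    """
    per_pop = (100 + 150 + 2 * n_controls + 2) // 3 + 1
    cfg = SyntheticConfig(3, per_pop, n_snps, 0.1,
                          seed=substream_seed(seed, "t4-sim"))
    cohort = simulate_populations(cfg)
    public, locals_ = split_federation(
        cohort, None, {"Ra": ["P1", "P2"]}, {"Ra": 100}
    )
    cohort, public, locals_ = _prepare(cohort, public, locals_)
    da = locals_["Ra"]
    model = fit_pca_model(public, 2)
    released = researcher_payload(
        model, da, epsilon, rng_seed=substream_seed(seed, "t4-noise")
    )
    member_ids = set(da.sample_ids)
    pool = [i for i, s in enumerate(cohort.sample_ids) if s not in member_ids]
    rng = np.random.default_rng(substream_seed(seed, "t4-controls"))
    chosen = rng.choice(pool, 2 * n_controls, replace=False)
    calib = cohort.take_samples(sorted(chosen[:n_controls].tolist()))
    fresh = cohort.take_samples(sorted(chosen[n_controls:].tolist()))
    from .pca import project_samples

    calib_d = _min_distances(project_samples(model, calib).coordinates, released)
    fresh_d = _min_distances(project_samples(model, fresh).coordinates, released)
    gamma = calibrate_threshold(calib_d, 0.05)
    return FprCalibration(
        threshold=gamma,
        empirical_fpr_percent=100.0 * float(np.mean(fresh_d < gamma)),
        n_controls=n_controls,
    )
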