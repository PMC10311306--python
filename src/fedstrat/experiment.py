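"""End-to-end replicated experiments on synthetic federations.

One experiment simulates a multi-population cohort, splits it into a public
training panel and researcher-local datasets, runs the full protocol (train,
project, perturb, aggregate, cluster) over a grid of privacy budgets, and
scores utility (accuracy versus the centralized benchmark, precision/recall
versus the generating population labels) and privacy (Euclidean-distance
membership-inference power against the first researcher's payload). Every
random stage draws its seed from :func:`fedstrat.seeding.substream_seed`, so
a configuration plus master seed determines every number exactly.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, qc_filter, restrict_to_snps
from .pca import fit_pca_model, hash_sample_ids, researcher_payload
from .privacy import AttackConfig, mi_power
from .seeding import substream_seed
from .server import (
    aggregate_metadata,
    centralized_benchmark,
    score_accuracy,
    score_precision_recall,
    stratify,
)
from .simulate import SyntheticConfig, simulate_populations, split_federation

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "replicate",
    "epsilon",
    "chosen_k",
    "accuracy",
    "precision",
    "recall",
    "power",
]


@dataclass
class FederationDesign:
    """How one simulated cohort is divided among the parties."""

    researcher_assignments: dict[str, list[str]]
    samples_per_party: dict[str, int]
    public_populations: list[str] | None = None  # None = all populations


@dataclass
class ExperimentConfig:
    synthetic: SyntheticConfig
    design: FederationDesign
    epsilons: list[float] = field(default_factory=lambda: [math.inf])
    n_components: int = 2
    k: int | str = "auto"
    n_replicates: int = 1
    n_attack: int = 100  # |G| = |H| for the membership attack
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        self.synthetic.validate()
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_attack < 1:
            raise ValueError("n_attack must be >= 1")
        for eps in self.epsilons:
            if not (eps > 0):
                raise ValueError(f"epsilon grid values must be positive, got {eps}")
        if self.k != "auto" and int(self.k) < 1:
            raise ValueError("k must be 'auto' or a positive integer")
        if not self.design.researcher_assignments:
            raise ValueError("at least one researcher is required")
        for name in self.design.researcher_assignments:
            if name not in self.design.samples_per_party:
                raise ValueError(f"no sample count for researcher {name!r}")


def _format_epsilon(eps: float) -> str:
    return "inf" if math.isinf(eps) else f"{eps:g}"


def _attack_sets(
    cohort: GenotypeMatrix,
    member_ids: set[str],
    n_attack: int,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Sample |H| members and |G| non-member controls from the cohort."""
    member_idx = [i for i, s in enumerate(cohort.sample_ids) if s in member_ids]
    control_idx = [i for i, s in enumerate(cohort.sample_ids) if s not in member_ids]
    if not member_idx or not control_idx:
        raise ValueError("cohort must contain both members and non-members")
    h = rng.choice(member_idx, size=min(n_attack, len(member_idx)), replace=False)
    g = rng.choice(control_idx, size=min(n_attack, len(control_idx)), replace=False)
    return cohort.take_samples(sorted(map(int, h))), cohort.take_samples(sorted(map(int, g)))


def run_experiment(cfg: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Run all replicates; return the per-run table and an averaged summary.

    When ``cfg.output_dir`` is set, writes ``results.tsv`` (one row per
    replicate × ε) and ``summary.json`` (replicate means per ε).
    """
    cfg.validate()
    rows: list[dict] = []
    researchers = list(cfg.design.researcher_assignments)
    for rep in range(cfg.n_replicates):
        t0 = time.perf_counter()
        sim_cfg = SyntheticConfig(
            n_populations=cfg.synthetic.n_populations,
            samples_per_population=cfg.synthetic.samples_per_population,
            n_snps=cfg.synthetic.n_snps,
            fst=cfg.synthetic.fst,
            maf_range=cfg.synthetic.maf_range,
            missing_rate=cfg.synthetic.missing_rate,
            seed=substream_seed(cfg.seed, "simulate", rep),
        )
        cohort = simulate_populations(sim_cfg)
        public, locals_ = split_federation(
            cohort,
            cfg.design.public_populations,
            cfg.design.researcher_assignments,
            cfg.design.samples_per_party,
        )
        # server-side QC defines the agreed SNP list for every party
        public = qc_filter(public, maf_min=0.01, missing_max=0.05)
        locals_ = {r: restrict_to_snps(g, public.snp_ids) for r, g in locals_.items()}
        cohort = restrict_to_snps(cohort, public.snp_ids)
        model = fit_pca_model(public, cfg.n_components)
        bench = centralized_benchmark(
            [locals_[r] for r in researchers],
            public,
            cfg.n_components,
            k=cfg.k,
            seed=substream_seed(cfg.seed, "benchmark", rep),
        )
        bench_by_id = dict(zip(bench.ids, bench.labels.tolist()))
        truth_pops = [p for r in researchers for p in locals_[r].population_labels]
        raw_ids = [s for r in researchers for s in locals_[r].sample_ids]
        hashed_of_raw = hash_sample_ids(raw_ids)
        bench_labels = np.array([bench_by_id[s] for s in raw_ids])

        first = researchers[0]
        member_ids = set(locals_[first].sample_ids)
        attack_rng = np.random.default_rng(substream_seed(cfg.seed, "attack-sets", rep))
        members_g, controls_g = _attack_sets(
            cohort, member_ids, cfg.n_attack, attack_rng
        )

        for ei, eps in enumerate(cfg.epsilons):
            payloads = [
                researcher_payload(
                    model,
                    locals_[r],
                    eps,
                    rng_seed=substream_seed(cfg.seed, "noise", rep, ei, r),
                )
                for r in researchers
            ]
            points = aggregate_metadata(payloads, sources=researchers)
            report = stratify(
                points, k=cfg.k, seed=substream_seed(cfg.seed, "cluster", rep, ei)
            )
            # combined rows follow researcher order, matching raw_ids
            assert list(points.hashed_ids) == hashed_of_raw
            attack = mi_power(
                AttackConfig(
                    model=model,
                    released=payloads[0],
                    control_genotypes=controls_g,
                    member_genotypes=members_g,
                )
            )
            precision, recall = score_precision_recall(report.labels, truth_pops)
            rows.append(
                {
                    "replicate": rep,
                    "epsilon": _format_epsilon(eps),
                    "chosen_k": report.chosen_k,
                    "accuracy": score_accuracy(report.labels, bench_labels),
                    "precision": precision,
                    "recall": recall,
                    "power": attack.power,
                }
            )
        log.info(
            "replicate %d/%d done in %.2fs",
            rep + 1,
            cfg.n_replicates,
            time.perf_counter() - t0,
        )

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    means = (
        table.groupby("epsilon", sort=False)[
            ["accuracy", "precision", "recall", "power"]
        ]
        .mean()
        .to_dict(orient="index")
    )
    summary = {
        "n_replicates": cfg.n_replicates,
        "seed": cfg.seed,
        "means_by_epsilon": means,
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return table, summary


# ---------------------------------------------------------------------------
# YAML configuration (CLI entry point)
# ---------------------------------------------------------------------------

def config_from_dict(payload: Mapping) -> ExperimentConfig:
    syn = payload.get("synthetic", {})
    maf_range = tuple(syn.get("maf_range", (0.05, 0.5)))
    synthetic = SyntheticConfig(
        n_populations=syn.get("n_populations", 3),
        samples_per_population=syn.get("samples_per_population", 50),
        n_snps=syn.get("n_snps", 2000),
        fst=syn.get("fst", 0.1),
        maf_range=maf_range,
        missing_rate=syn.get("missing_rate", 0.0),
        seed=syn.get("seed", 0),
    )
    des = payload["design"]
    design = FederationDesign(
        researcher_assignments={
            str(k): [str(p) for p in v]
            for k, v in des["researcher_assignments"].items()
        },
        samples_per_party={str(k): int(v) for k, v in des["samples_per_party"].items()},
        public_populations=(
            [str(p) for p in des["public_populations"]]
            if des.get("public_populations") is not None
            else None
        ),
    )
    epsilons = [
        math.inf if (isinstance(e, str) and e.lower() in ("inf", "infinity")) else float(e)
        for e in payload.get("epsilons", ["inf"])
    ]
    return ExperimentConfig(
        synthetic=synthetic,
        design=design,
        epsilons=epsilons,
        n_components=payload.get("n_components", 2),
        k=payload.get("k", "auto"),
        n_replicates=payload.get("n_replicates", 1),
        n_attack=payload.get("n_attack", 100),
        seed=payload.get("seed", 0),
        output_dir=payload.get("output_dir"),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
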