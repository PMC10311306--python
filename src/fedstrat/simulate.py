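"""Synthetic multi-population genotype data.

Populations are simulated under the Balding–Nichols model: each SNP has an
ancestral allele frequency q drawn uniformly from ``maf_range``; population k
draws its own frequency q_k ~ Beta(q(1-F_ST)/F_ST, (1-q)(1-F_ST)/F_ST), so
that E[q_k] = q and Var[q_k] = F_ST * q(1-q); individual dosages are then
Binomial(2, q_k). F_ST controls how strongly populations diverge and hence
how separable they are in PCA space.

The module also splits one simulated cohort into the parties of the
federation: a public training panel held by the server and disjoint local
datasets held by the researchers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class SyntheticConfig:
    """Parameters of one simulated multi-population cohort.

    ``samples_per_population`` may be a single count (same for every
    population) or one count per population.
    """

    n_populations: int = 3
    samples_per_population: int | Sequence[int] = 50
    n_snps: int = 2000
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def counts(self) -> list[int]:
        if isinstance(self.samples_per_population, int):
            return [self.samples_per_population] * self.n_populations
        return list(self.samples_per_population)

    def validate(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        counts = self.counts()
        if len(counts) != self.n_populations:
            raise ValueError("samples_per_population length must equal n_populations")
        if any(c < 1 for c in counts):
            raise ValueError("every population needs at least one sample")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


def population_names(n: int) -> list[str]:
    """Canonical population labels P1..Pn."""
    return [f"P{k + 1}" for k in range(n)]


def simulate_populations(
    cfg: SyntheticConfig, return_frequencies: bool = False
) -> GenotypeMatrix | tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Draw a Balding–Nichols genotype matrix; deterministic given cfg.seed.

    With ``return_frequencies=True`` also returns the generating frequencies
    (``ancestral``: length-m array; ``population``: K × m array), which serve
    as reference allele frequencies for the likelihood-ratio membership test.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.counts()
    m = cfg.n_snps
    lo, hi = cfg.maf_range
    q = rng.uniform(lo, hi, size=m)
    ratio = (1.0 - cfg.fst) / cfg.fst
    pop_freq = rng.beta(q * ratio, (1.0 - q) * ratio, size=(cfg.n_populations, m))
    # guard against numerically degenerate Beta draws
    pop_freq = np.clip(pop_freq, 1e-12, 1.0 - 1e-12)

    blocks = [
        rng.binomial(2, pop_freq[k], size=(counts[k], m)).astype(float)
        for k in range(cfg.n_populations)
    ]
    values = np.vstack(blocks)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = np.nan

    names = population_names(cfg.n_populations)
    labels = [names[k] for k in range(cfg.n_populations) for _ in range(counts[k])]
    sample_ids = [f"ind{i:05d}" for i in range(values.shape[0])]
    snp_ids = [f"snp{j:05d}" for j in range(m)]
    g = GenotypeMatrix(values, sample_ids, snp_ids, labels)
    if return_frequencies:
        return g, {"ancestral": q, "population": pop_freq}
    return g


def split_federation(
    g: GenotypeMatrix,
    public_populations: set[str] | Sequence[str] | None,
    researcher_assignments: Mapping[str, set[str] | Sequence[str]],
    samples_per_party: Mapping[str, int],
) -> tuple[GenotypeMatrix, dict[str, GenotypeMatrix]]:
    """Split one labelled cohort into a public panel and local datasets.

    Each researcher receives ``samples_per_party[name]`` samples drawn
    round-robin (in row order) from its assigned populations; the public
    panel is the remainder restricted to ``public_populations`` (all
    populations when None). Parties are processed in mapping order and
    sample sets are disjoint by construction.
    """
    if g.population_labels is None:
        raise ValueError("split_federation requires population labels")
    labels = np.asarray(g.population_labels)
    available: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        available.setdefault(lab, []).append(i)

    locals_: dict[str, GenotypeMatrix] = {}
    for name, pops in researcher_assignments.items():
        pops = sorted(set(map(str, pops)))
        want = samples_per_party[name]
        chosen: list[int] = []
        pools = {p: available.get(p, []) for p in pops}
        for p in pops:
            if p not in available:
                raise ValueError(f"population {p!r} not present in the cohort")
        while len(chosen) < want:
            progressed = False
            for p in pops:
                if len(chosen) >= want:
                    break
                if pools[p]:
                    chosen.append(pools[p].pop(0))
                    progressed = True
            if not progressed:
                short = want - len(chosen)
                raise ValueError(
                    f"insufficient samples for researcher {name!r}: populations "
                    f"{pops} exhausted with {short} still required"
                )
        locals_[name] = g.take_samples(sorted(chosen))

    if public_populations is None:
        public_pops = set(available)
    else:
        public_pops = set(map(str, public_populations))
    remaining = [i for p in sorted(available) for i in available[p] if p in public_pops]
    if not remaining:
        raise ValueError("public panel is empty after assigning researcher samples")
    public = g.take_samples(sorted(remaining))
    return public, locals_
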