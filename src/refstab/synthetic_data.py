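"""Seeded generator of synthetic Ct tables and dilution series.

No raw Ct data accompany most published stability studies, so algorithm
behaviour is validated on simulated tables whose generative model mirrors
the assumptions the algorithms themselves make.  A Ct observation is

    Ct(sample s, bio rep b, gene i, tech rep t)
        = mu_i + lambda_{s,b} + delta_{i, group(s)} + eps_{i,s,b} + tau_t

with mu_i the gene's baseline cycle number, lambda a shared per-sample
loading/template shift (Normal(0, sigma_load) — exactly the effect the
ratio-based methods cancel), delta_ig a systematic group/tissue shift for
unstable genes, eps gene-specific biological noise (Normal(0, sigma_bio_i))
and tau technical replicate noise (Normal(0, sigma_tech)).  All noise is
Normal on the Ct (log2) scale, consistent with the algorithms operating on
Ct and log2 quantities.

Ground truth for recovery tests: a gene's true instability is
sqrt(Var_g(delta_ig, group-size weighted) + sigma_bio_i^2) — zero only for
a gene with no group shifts and no biological noise.

Determinism: the same seed yields a bit-identical table.  The loading,
biological and technical noise streams are drawn from independent child
seeds and stored as standard-normal draws scaled by their SDs, so changing
one SD rescales that component without re-randomising the others — which
makes "same seed, 10x sigma_load" comparisons exact, not just statistical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .ct_model import CtRecord, CtTable
from .quantification import slope_from_efficiency

__all__ = [
    "GeneSpec",
    "SampleSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_ct_table",
    "simulate_dilution_series",
]


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    mu: float                       # baseline Ct, cycles
    sigma_bio: float = 0.0          # biological replicate SD, cycles
    group_deltas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.mu < 45):
            raise ValueError(f"{self.gene_id}: baseline Ct must be in (0, 45)")
        if self.sigma_bio < 0:
            raise ValueError(f"{self.gene_id}: sigma_bio must be >= 0")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str = "all"
    n_bio_reps: int = 3
    n_tech_reps: int = 3

    def __post_init__(self) -> None:
        if self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ValueError(f"{self.sample_id}: replicate counts must be >= 1")


@dataclass
class SimConfig:
    genes: list[GeneSpec]
    samples: list[SampleSpec]
    sigma_load: float = 0.3     # SD of the shared per-sample loading shift
    sigma_tech: float = 0.1     # SD of technical replicate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_load < 0 or self.sigma_tech < 0:
            raise ValueError("noise SDs must be >= 0")
        sample_groups = {s.group for s in self.samples}
        for g in self.genes:
            extra = set(g.group_deltas) - sample_groups
            if extra:
                raise ValueError(
                    f"{g.gene_id}: group_deltas for unknown groups {sorted(extra)}"
                )
        if len({g.gene_id for g in self.genes}) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len({s.sample_id for s in self.samples}) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(open(path).read())
        genes = [
            GeneSpec(
                gene_id=g["gene_id"],
                mu=float(g["mu"]),
                sigma_bio=float(g.get("sigma_bio", 0.0)),
                group_deltas={k: float(v) for k, v in g.get("group_deltas", {}).items()},
            )
            for g in data["genes"]
        ]
        samples = [
            SampleSpec(
                sample_id=s["sample_id"],
                group=s.get("group", "all"),
                n_bio_reps=int(s.get("n_bio_reps", 3)),
                n_tech_reps=int(s.get("n_tech_reps", 3)),
            )
            for s in data["samples"]
        ]
        return cls(
            genes=genes,
            samples=samples,
            sigma_load=float(data.get("sigma_load", 0.3)),
            sigma_tech=float(data.get("sigma_tech", 0.1)),
            seed=int(data.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    true_stability: dict[str, float]
    true_rank: dict[str, float]


def _ground_truth(cfg: SimConfig) -> GroundTruth:
    from scipy import stats

    weights = {}
    for s in cfg.samples:
        weights[s.group] = weights.get(s.group, 0) + s.n_bio_reps
    total = sum(weights.values())
    stabilities = []
    for g in cfg.genes:
        deltas = np.array([g.group_deltas.get(grp, 0.0) for grp in weights])
        w = np.array([weights[grp] for grp in weights]) / total
        mean_d = float(w @ deltas)
        var_d = float(w @ (deltas - mean_d) ** 2)
        stabilities.append(np.sqrt(var_d + g.sigma_bio**2))
    ranks = stats.rankdata(stabilities, method="average")
    return GroundTruth(
        true_stability={g.gene_id: float(v) for g, v in zip(cfg.genes, stabilities)},
        true_rank={g.gene_id: float(r) for g, r in zip(cfg.genes, ranks)},
    )


def simulate_ct_table(cfg: SimConfig) -> tuple[CtTable, GroundTruth]:
    """Draw a replicate-level Ct table from the additive generative model.

    Each biological replicate of a condition becomes its own sample
    (``condition.b1`` etc. when ``n_bio_reps > 1``), carrying its own
    loading shift and biological noise; technical replicates (``t1``...)
    share those and differ only by technical noise.  Keeping biological
    replicates as separate samples preserves the biological variance the
    stability statistics are supposed to measure.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_load, ss_bio, ss_tech = root.spawn(3)
    rng_load = np.random.default_rng(ss_load)
    rng_bio = np.random.default_rng(ss_bio)
    rng_tech = np.random.default_rng(ss_tech)

    k = len(cfg.genes)
    records: list[CtRecord] = []
    for s in cfg.samples:
        for b in range(1, s.n_bio_reps + 1):
            sid = s.sample_id if s.n_bio_reps == 1 else f"{s.sample_id}.b{b}"
            lam = cfg.sigma_load * rng_load.standard_normal()
            eps = rng_bio.standard_normal(k)
            for i, g in enumerate(cfg.genes):
                base = (
                    g.mu
                    + lam
                    + g.group_deltas.get(s.group, 0.0)
                    + g.sigma_bio * eps[i]
                )
                tau = cfg.sigma_tech * rng_tech.standard_normal(s.n_tech_reps)
                for t in range(1, s.n_tech_reps + 1):
                    records.append(
                        CtRecord(sid, g.gene_id, f"t{t}", float(base + tau[t - 1]))
                    )
    return CtTable(records), _ground_truth(cfg)


def benchmark_scenario(seed: int = 2020) -> SimConfig:
    """Packaged end-to-end scenario: a realistic candidate panel.

    Ten candidate genes over four tissue/stage groups (shoot and root at two
    seedling stages, three biological x three technical replicates each),
    emulating the structure of a reference-gene screen: two planted stable
    genes (sigma_bio = 0.05 cycles), a moderate mid-panel (0.3-0.6 cycles,
    the pairwise-SD range typical of published screens), and three unstable
    genes combining large biological noise with systematic tissue or stage
    shifts (the behaviour of differentially expressed homeolog pools and of
    a very highly expressed rRNA).  Loading SD 0.15 cycles reflects
    carefully equalised template input; technical SD 0.1 cycles.
    """
    shoot_root = lambda d: {"root_2leaf": d, "root_3leaf": d}
    stages = lambda d: {"shoot_3leaf": d, "root_3leaf": d}
    genes = [
        GeneSpec("REF1", 19.5, 0.05),
        GeneSpec("REF2", 21.0, 0.05),
        GeneSpec("MID1", 18.5, 0.30),
        GeneSpec("MID2", 22.5, 0.40),
        GeneSpec("MID3", 24.0, 0.45),
        GeneSpec("MID4", 20.5, 0.50),
        GeneSpec("MID5", 23.0, 0.60),
        GeneSpec("VAR1", 25.0, 0.80, shoot_root(0.8)),
        GeneSpec("VAR2", 26.0, 1.00, stages(1.0)),
        GeneSpec("RRNA", 8.0, 1.20, shoot_root(-1.2)),
    ]
    samples = [
        SampleSpec("shoot2", "shoot_2leaf", 3, 3),
        SampleSpec("root2", "root_2leaf", 3, 3),
        SampleSpec("shoot3", "shoot_3leaf", 3, 3),
        SampleSpec("root3", "root_3leaf", 3, 3),
    ]
    return SimConfig(genes=genes, samples=samples, sigma_load=0.15,
                     sigma_tech=0.1, seed=seed)


def planted_pair_scenario(seed: int, n_samples: int = 100) -> SimConfig:
    """Recovery benchmark: two planted stable genes among a noisy panel.

    Eight genes, two with sigma_bio = 0.05 cycles and six with >= 0.8, over
    ``n_samples`` independent biological samples — the regime where every
    stability algorithm should place the planted pair on top.
    """
    sigmas = [0.05, 0.05, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3]
    genes = [
        GeneSpec(f"g{i + 1}", 18.0 + i, s) for i, s in enumerate(sigmas)
    ]
    samples = [SampleSpec(f"s{j}", "all", 1, 1) for j in range(n_samples)]
    return SimConfig(genes=genes, samples=samples, sigma_load=0.3,
                     sigma_tech=0.1, seed=seed)


def simulate_dilution_series(
    efficiency_percent: float,
    intercept: float = 20.0,
    levels: int = 5,
    sigma_tech: float = 0.0,
    seed: int = 0,
    dilution_step: float = -1.0,
) -> list[tuple[float, float]]:
    """Simulate a standard-curve dilution series.

    Dilution levels sit at log10 dilutions 0, step, 2*step, ...; Ct follows
    the line with slope -1/log10(1 + E/100) plus technical noise.
    """
    if not (50.0 <= efficiency_percent <= 150.0):
        raise ValueError("efficiency_percent must be within [50, 150]")
    if levels < 3:
        raise ValueError("a standard curve needs >=3 dilution levels")
    rng = np.random.default_rng(seed)
    slope = slope_from_efficiency(efficiency_percent)
    out = []
    for lvl in range(levels):
        x = dilution_step * lvl
        ct = intercept + slope * x + sigma_tech * rng.standard_normal()
        out.append((float(x), float(ct)))
    return out
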