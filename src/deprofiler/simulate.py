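"""Synthetic count matrices and qPCR Ct tables with known ground truth.

The count generator emulates a 2x2 factorial bulk RNA-seq design (genotype
in {wt, ko} x transgene in {nontg, tg}, n per group configurable, default 5)
with planted co-regulated gene programs, negative-binomial noise
(variance = mu + phi * mu^2) and log-normal library-depth variation. Every
planted effect is recorded in a truth table so downstream estimators can be
checked for recovery.

Seeding: a single base seed per scenario; independent generator streams for
baseline means, library factors and count sampling are derived as
``np.random.default_rng([seed, stream_index])`` so each stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Contrast, CountMatrix, Group, InputError, SampleMeta, default_contrasts
from .qpcr import CtTable

GROUP_ORDER: tuple[Group, ...] = (
    ("wt", "nontg"),
    ("wt", "tg"),
    ("ko", "nontg"),
    ("ko", "tg"),
)


@dataclass
class PlantedProgram:
    """A block of co-regulated genes with per-group log2 expression offsets.

    ``amplitude_range`` spreads per-gene response strength evenly over the
    block (co-regulated genes never respond with identical amplitude); the
    i-th gene's offsets are the group effects scaled by a factor
    interpolated linearly across the range. (1, 1) gives uniform amplitude.
    """

    name: str
    gene_indices: Sequence[int]
    effect: Mapping[Group, float]
    amplitude_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.gene_indices = list(self.gene_indices)
        self.effect = {tuple(k): float(v) for k, v in self.effect.items()}
        if self.name != "null" and not any(v != 0.0 for v in self.effect.values()):
            raise InputError(f"program {self.name!r} has all-zero offsets")
        lo, hi = self.amplitude_range
        if lo <= 0 or hi < lo:
            raise InputError(
                f"program {self.name!r}: amplitude_range must satisfy 0 < lo <= hi"
            )

    def offset(self, group: Group) -> float:
        return self.effect.get(tuple(group), 0.0)

    def amplitudes(self) -> np.ndarray:
        n = len(self.gene_indices)
        lo, hi = self.amplitude_range
        if n == 1:
            return np.array([(lo + hi) / 2.0])
        return np.linspace(lo, hi, n)


@dataclass
class SyntheticScenario:
    """Full description of a synthetic 2x2 RNA-seq experiment."""

    n_genes: int = 2000
    n_per_group: int = 5
    baseline_log2_mean: tuple[float, float] = (5.0, 2.0)  # (mean, sd)
    dispersion_phi0: float = 0.05
    dispersion_a: float = 1.0  # phi_g = phi0 + a / mu_g
    library_size_log_sd: float = 0.2
    background_effect_sd: float = 0.0  # per-gene per-group log2 "biological" offsets
    programs: list[PlantedProgram] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InputError("n_per_group must be >= 2")
        if self.dispersion_phi0 < 0 or self.dispersion_a < 0:
            raise InputError("dispersion parameters must be >= 0")
        seen: set[int] = set()
        for prog in self.programs:
            for i in prog.gene_indices:
                if not (0 <= i < self.n_genes):
                    raise InputError(
                        f"program {prog.name!r}: gene index {i} out of range "
                        f"(n_genes={self.n_genes})"
                    )
                if i in seen:
                    raise InputError(
                        f"program gene index {i} assigned to more than one program"
                    )
                seen.add(i)


def default_scenario(name: str, seed: int = 0) -> SyntheticScenario:
    """Preset scenarios.

    - ``ad_like``: 2000 genes, n=5/group, four disjoint 60-gene programs
      with maximally separated (tetrahedral) differential-profile
      directions. Every program carries a nonzero genotype x transgene
      interaction component (the clustering stage selects genes by
      interaction FDR, so programs must be interaction-detectable to be
      clusterable): an ISG-like program induced mainly in (ko, tg); a
      DAM-like program up with the transgene in wt; a genotype program up
      in (ko, nontg); and a weaker program down-regulated by either
      perturbation.
    - ``null``: 2000 genes, no programs.
    - ``two_blob``: 120 genes, two 60-gene programs with distinct
      directions and no null background.
    """
    # The four pairwise-contrast vectors of a 2x2 design span a rank-3
    # subspace; these group-offset sets place the programs' differential-
    # profile directions at the vertices of a regular tetrahedron there
    # (pairwise cosine -1/3, the best separation four directions admit).
    # Three programs are strong and homogeneous (|log2 interaction| = 2);
    # the fourth ramps its per-gene amplitude from 0.4 to 1.0 of that, so
    # its genes grade continuously from barely-detectable into moderate
    # significance the way a modest real program does.
    if name == "ad_like":
        programs = [
            PlantedProgram(
                "isg_interaction",
                range(0, 60),
                {("wt", "tg"): 0.414, ("ko", "nontg"): 0.414, ("ko", "tg"): 2.828},
            ),
            PlantedProgram(
                "dam_transgene",
                range(60, 120),
                {("wt", "tg"): 2.414, ("ko", "nontg"): -0.414, ("ko", "tg"): 0.0},
            ),
            PlantedProgram(
                "genotype_up",
                range(120, 180),
                {("wt", "tg"): -0.414, ("ko", "nontg"): 2.414, ("ko", "tg"): 0.0},
            ),
            PlantedProgram(
                "transgene_down",
                range(180, 240),
                {("wt", "tg"): -2.414, ("ko", "nontg"): -2.414, ("ko", "tg"): -2.828},
                amplitude_range=(0.4, 1.0),
            ),
        ]
        return SyntheticScenario(
            n_genes=2000,
            programs=programs,
            seed=seed,
            dispersion_phi0=0.1,
            baseline_log2_mean=(5.0, 1.2),
        )
    if name == "null":
        # homogeneous dispersion: the calibration null matches the
        # common/tagwise estimator's model, so rejection rates measure the
        # tests themselves rather than dispersion-trend mismatch
        return SyntheticScenario(
            n_genes=2000, programs=[], seed=seed, dispersion_a=0.0
        )
    if name == "two_blob":
        # exactly two symmetric strong blobs, no null background: every gene
        # belongs to a program, so the selected profile set is two clean,
        # equally-strong twins
        programs = [
            PlantedProgram(
                "blob_interaction",
                range(0, 60),
                {("wt", "tg"): 0.414, ("ko", "nontg"): 0.414, ("ko", "tg"): 2.828},
            ),
            PlantedProgram(
                "blob_transgene",
                range(60, 120),
                {("wt", "tg"): 2.414, ("ko", "nontg"): -0.414, ("ko", "tg"): 0.0},
            ),
        ]
        return SyntheticScenario(
            n_genes=120,
            programs=programs,
            seed=seed,
            dispersion_phi0=0.1,
            baseline_log2_mean=(5.0, 0.8),
        )
    raise InputError(
        f"unknown scenario {name!r}; presets: ad_like, null, two_blob"
    )


def _sample_names(n_per_group: int) -> list[tuple[str, Group]]:
    names = []
    for geno, tg in GROUP_ORDER:
        for i in range(n_per_group):
            names.append((f"{geno}_{tg}_{i + 1}", (geno, tg)))
    return names


def _program_offsets(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """(G x 4 group-offset matrix, per-gene program labels)."""
    offsets = np.zeros((scenario.n_genes, len(GROUP_ORDER)))
    program = np.array(["null"] * scenario.n_genes, dtype=object)
    for prog in scenario.programs:
        amps = prog.amplitudes()
        for a, gi in zip(amps, prog.gene_indices):
            program[gi] = prog.name
            for j, grp in enumerate(GROUP_ORDER):
                offsets[gi, j] = a * prog.offset(grp)
    return offsets, program


def truth_table(
    scenario: SyntheticScenario, contrasts: Sequence[Contrast] | None = None
) -> pd.DataFrame:
    """Planted per-gene truth: program label, interaction effect, contrast log2FCs."""
    if contrasts is None:
        contrasts = default_contrasts()
    gene_ids = [f"g{i:05d}" for i in range(scenario.n_genes)]
    offsets, program = _program_offsets(scenario)
    col = {grp: j for j, grp in enumerate(GROUP_ORDER)}
    out = pd.DataFrame({"gene_id": gene_ids, "program": program}).set_index("gene_id")
    # interaction on the log2 scale: (koTg - wtTg) - (koNontg - wtNontg)
    out["true_interaction_log2"] = (
        offsets[:, col[("ko", "tg")]]
        - offsets[:, col[("wt", "tg")]]
        - offsets[:, col[("ko", "nontg")]]
        + offsets[:, col[("wt", "nontg")]]
    )
    out["has_interaction"] = out["true_interaction_log2"] != 0.0
    for c in contrasts:
        out[f"true_log2fc_{c.name}"] = (
            offsets[:, col[tuple(c.group_a)]] - offsets[:, col[tuple(c.group_b)]]
        )
    return out


def generate_counts(
    scenario: SyntheticScenario,
) -> tuple[CountMatrix, list[SampleMeta], pd.DataFrame]:
    """Draw a count matrix from the scenario's NB model.

    Counts for gene g in sample s are NB with mean
    ``library_factor_s * 2^(baseline_g + program_offset_g(group(s)))`` and
    dispersion ``phi_g = phi0 + a / mu_g`` (mu_g the baseline mean), i.e.
    variance mu + phi mu^2. Deterministic given the scenario seed.
    """
    rng_base = np.random.default_rng([scenario.seed, 0])
    rng_lib = np.random.default_rng([scenario.seed, 1])
    rng_counts = np.random.default_rng([scenario.seed, 2])

    G = scenario.n_genes
    mean, sd = scenario.baseline_log2_mean
    baseline = rng_base.normal(mean, sd, size=G)

    samples = _sample_names(scenario.n_per_group)
    S = len(samples)
    lib_factors = np.exp(rng_lib.normal(0.0, scenario.library_size_log_sd, size=S))

    col = {grp: j for j, grp in enumerate(GROUP_ORDER)}
    offsets, _ = _program_offsets(scenario)
    if scenario.background_effect_sd > 0:
        # small idiosyncratic per-gene condition responses: real transcriptomes
        # have no exactly-null genes
        rng_bg = np.random.default_rng([scenario.seed, 4])
        offsets = offsets + rng_bg.normal(
            0.0, scenario.background_effect_sd, size=offsets.shape
        )

    group_idx = np.array([col[grp] for _, grp in samples])
    log2_mu = baseline[:, None] + offsets[:, group_idx]
    mu = lib_factors[None, :] * np.exp2(log2_mu)

    mu_base = np.exp2(baseline)
    phi = scenario.dispersion_phi0 + np.divide(
        scenario.dispersion_a, mu_base, out=np.zeros_like(mu_base),
        where=mu_base > 0,
    )

    counts = np.empty((G, S), dtype=np.int64)
    poisson = phi <= 0
    if poisson.any():
        counts[poisson] = rng_counts.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / phi[nb]
        p = r[:, None] / (r[:, None] + mu[nb])
        counts[nb] = rng_counts.negative_binomial(r[:, None], p)

    gene_ids = [f"g{i:05d}" for i in range(G)]
    df = pd.DataFrame(counts, index=gene_ids, columns=[s for s, _ in samples])
    df.index.name = "gene_id"
    metas = [SampleMeta(s, grp[0], grp[1]) for s, grp in samples]
    return CountMatrix(df), metas, truth_table(scenario)


# ---------------------------------------------------------------------------
# qPCR Ct generator


@dataclass
class CtDesign:
    """A knockdown-style qPCR experiment with known relative expressions.

    ``rel_expr`` maps (condition, target) to the true expression relative to
    the control condition; conditions or targets not listed default to 1.0.
    Reference-gene Ct is unaffected by condition.
    """

    targets: list[str]
    conditions: list[str]
    control: str
    reference: str = "RNU1A1"
    n_replicates: int = 3
    n_technical: int = 1
    rel_expr: Mapping[tuple[str, str], float] = field(default_factory=dict)
    base_ct: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.control not in self.conditions:
            raise InputError("control condition must be listed in conditions")
        for (cond, tgt), v in self.rel_expr.items():
            if v <= 0:
                raise InputError(
                    f"relative expression for ({cond}, {tgt}) must be > 0, got {v}"
                )

    def true_rel(self, condition: str, target: str) -> float:
        if condition == self.control:
            return 1.0
        return float(self.rel_expr.get((condition, target), 1.0))


def generate_ct_table(design: CtDesign, seed: int = 0) -> CtTable:
    """Simulate Ct values: Ct = base_ct - log2(relative expression) + noise.

    One biological replicate = one sample; ``n_technical`` repeated wells per
    (sample, gene) share the sample's biology and differ only by technical
    Gaussian noise (sd ``noise_sd`` cycles).
    """
    rng = np.random.default_rng([seed, 3])
    rows = []
    genes = list(design.targets) + [design.reference]
    for cond in design.conditions:
        for rep in range(1, design.n_replicates + 1):
            sample = f"{cond}_{rep}"
            for gene in genes:
                base = float(design.base_ct.get(gene, 22.0))
                if gene == design.reference:
                    true_ct = base
                else:
                    true_ct = base - np.log2(design.true_rel(cond, gene))
                for tech in range(1, design.n_technical + 1):
                    noise = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": sample,
                            "condition": cond,
                            "target": gene,
                            "ct": true_ct + noise,
                            "replicate": tech,
                        }
                    )
    return CtTable(
        pd.DataFrame(rows), reference=design.reference, control=design.control
    )
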