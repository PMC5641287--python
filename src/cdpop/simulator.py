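"""Synthetic NAM designs: doubled-haploid families, panels, phenotypes.

The generator emulates the structure of a maize-style nested association
mapping (NAM) design: several biparental doubled-haploid (DH) families,
each derived from the cross of a diverse donor inbred with one shared
central inbred line, optionally accompanied by a diverse panel of
unrelated inbred lines that includes the NAM parents.

Meiosis follows Haldane's model (no crossover interference): between
adjacent loci d centimorgans apart a recombination occurs with
probability (1 - exp(-2d/100)) / 2, independently across intervals and
chromosomes. A DH line is one F1 gamete with its genome doubled, so DH
genotypes are fully homozygous (dosage 0 or 1, never 0.5).

Traits are polygenic: additive effects are drawn at a chosen set of loci
and the true breeding value (TBV) of an individual is the sum of
(dosage - 0.5) * effect over loci — the centred coding makes effects
symmetric under relabelling of the alleles. Residual variance is set
from the realized TBV variance so that the target heritability holds by
construction.

``monte_carlo_reliability`` is the simulation oracle for the CD: it
draws genetic values from N(0, K), phenotypes with residual variance
lambda (on the sigma_g^2 = 1 scale), solves G-BLUP, and reports the
empirical squared correlation between the true and predicted contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gblup import DEFAULT_RIDGE, incidence, ridged
from .genotypes import GenotypeMatrix, KinshipMatrix


@dataclass
class GeneticMap:
    """Marker positions in centimorgans, grouped by chromosome."""

    locus_ids: list[str]
    chromosome: np.ndarray
    position_cm: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.chromosome = np.asarray(self.chromosome)
        self.position_cm = np.asarray(self.position_cm, dtype=float)
        L = len(self.locus_ids)
        if self.chromosome.shape != (L,) or self.position_cm.shape != (L,):
            raise ValueError("chromosome and position arrays must match locus_ids")
        if L and self.position_cm.min() < 0:
            raise ValueError("positions must be >= 0")
        for chrom in dict.fromkeys(self.chromosome.tolist()):
            pos = self.position_cm[self.chromosome == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted within chromosome {chrom!r}")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 5,
        loci_per_chromosome: int = 60,
        length_cm: float = 150.0,
    ) -> "GeneticMap":
        """Evenly spaced loci on equally long chromosomes."""
        ids, chroms, pos = [], [], []
        for c in range(1, n_chromosomes + 1):
            grid = np.linspace(0.0, length_cm, loci_per_chromosome)
            for k, x in enumerate(grid, start=1):
                ids.append(f"c{c}_l{k:03d}")
                chroms.append(f"chr{c}")
                pos.append(x)
        return cls(ids, np.array(chroms), np.array(pos))

    def chromosome_blocks(self) -> list[np.ndarray]:
        """Locus index arrays, one per chromosome, in map order."""
        return [
            np.flatnonzero(self.chromosome == chrom)
            for chrom in dict.fromkeys(self.chromosome.tolist())
        ]


@dataclass
class SimulatedPopulation:
    """Genotypes plus (optionally) the trait ground truth that generated them."""

    genotypes: GenotypeMatrix
    true_breeding_values: pd.Series | None = None
    marker_effects: pd.Series | None = None
    phenotypes: pd.Series | None = None
    target_h2: float | None = None
    mu: float = 0.0
    sigma_e2: float | None = None
    seed: int | None = None


def haldane_recombination_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination probability between loci d centimorgans apart."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_founders(
    n_founders: int,
    gmap: GeneticMap,
    maf_low: float = 0.1,
    seed: int = 0,
    id_prefix: str = "founder",
) -> GenotypeMatrix:
    """Fully homozygous founder lines with independent loci.

    Each locus gets a reference-allele frequency drawn uniformly in
    [maf_low, 1 - maf_low]; founder dosages are independent Bernoulli
    draws at that frequency. Linkage disequilibrium then arises in the
    descendants through co-inheritance, not in the founders themselves.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, 1.0 - maf_low, size=gmap.n_loci)
    values = (rng.random((n_founders, gmap.n_loci)) < freqs).astype(float)
    ids = [f"{id_prefix}_{k + 1:03d}" for k in range(n_founders)]
    return GenotypeMatrix(ids, list(gmap.locus_ids), values)


def _gametes(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """n haploid gametes of the F1 of two homozygous parents."""
    out = np.empty((n, gmap.n_loci))
    for block in gmap.chromosome_blocks():
        pos = gmap.position_cm[block]
        r = haldane_recombination_fraction(np.diff(pos))
        start = rng.integers(0, 2, size=n)
        crossovers = rng.random((n, len(r))) < r
        # parity of crossovers so far selects the parental strand per locus
        strand = np.column_stack([start, (start[:, None] + np.cumsum(crossovers, axis=1)) % 2])
        out[:, block] = np.where(strand == 0, parent1[block], parent2[block])
    return out


def simulate_dh_family(
    parent1: np.ndarray,
    parent2: np.ndarray,
    n_dh: int,
    gmap: GeneticMap,
    seed: int = 0,
    id_prefix: str = "dh",
) -> GenotypeMatrix:
    """Doubled-haploid lines from the cross of two homozygous parents.

    Each DH line is a single F1 gamete (one meiosis under Haldane's
    model) with its genome doubled, so every dosage is 0 or 1.
    """
    parent1 = np.asarray(parent1, dtype=float)
    parent2 = np.asarray(parent2, dtype=float)
    for name, par in (("parent1", parent1), ("parent2", parent2)):
        if par.shape != (gmap.n_loci,):
            raise ValueError(f"{name} must have one dosage per locus")
        if not np.isin(par, (0.0, 1.0)).all():
            raise ValueError(f"{name} is not fully homozygous (values not in {{0, 1}})")
    rng = np.random.default_rng(seed)
    values = _gametes(parent1, parent2, n_dh, gmap, rng)
    ids = [f"{id_prefix}_{k + 1:04d}" for k in range(n_dh)]
    return GenotypeMatrix(ids, list(gmap.locus_ids), values)


def simulate_ancestral_inbreds(
    n_lines: int,
    ancestors: GenotypeMatrix,
    gmap: GeneticMap,
    seed: int = 0,
    id_prefix: str = "line",
) -> GenotypeMatrix:
    """Inbred lines bred from random crosses within a small ancestral pool.

    Each line is one DH offspring of a random (unordered, distinct) pair
    of ancestors. Lines sharing an ancestor are related (kinship about
    0.5 on the pedigree scale), lines from disjoint pairs are not — the
    heterogeneous relatedness typical of elite breeding pools, where NAM
    parents and panel members alike descend from few key founders.
    """
    if ancestors.n_individuals < 2:
        raise ValueError("need at least 2 ancestors")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_lines):
        a, b = rng.choice(ancestors.n_individuals, size=2, replace=False)
        dh = simulate_dh_family(
            ancestors.values[a],
            ancestors.values[b],
            1,
            gmap,
            seed=int(rng.integers(2**31)),
            id_prefix=f"{id_prefix}_{k + 1:03d}",
        )
        rows.append(dh.values[0])
    ids = [f"{id_prefix}_{k + 1:03d}" for k in range(n_lines)]
    return GenotypeMatrix(ids, list(gmap.locus_ids), np.array(rows))


def simulate_nam(
    central_parent: np.ndarray,
    donor_parents: GenotypeMatrix,
    family_sizes: Sequence[int],
    gmap: GeneticMap,
    seed: int = 0,
    family_prefix: str = "F",
) -> SimulatedPopulation:
    """A NAM design: one DH family per donor, all sharing the central parent."""
    if len(family_sizes) != donor_parents.n_individuals:
        raise ValueError("one family size per donor parent required")
    if any(s <= 0 for s in family_sizes):
        raise ValueError("family sizes must be positive")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(family_sizes))
    blocks, ids, family_of = [], [], {}
    for d, (size, child) in enumerate(zip(family_sizes, children)):
        label = f"{family_prefix}{d + 1:02d}"
        fam = simulate_dh_family(
            central_parent,
            donor_parents.values[d],
            size,
            gmap,
            seed=int(child.generate_state(1)[0] % (2**31)),
            id_prefix=label,
        )
        blocks.append(fam.values)
        ids.extend(fam.individual_ids)
        family_of.update({i: label for i in fam.individual_ids})
    G = GenotypeMatrix(
        ids, list(gmap.locus_ids), np.vstack(blocks), family_of=family_of
    )
    return SimulatedPopulation(genotypes=G, seed=seed)


def simulate_phenotypes(
    G: GenotypeMatrix,
    h2: float,
    n_qtl: int | str = "all",
    effect_sd: float = 1.0,
    mu: float = 0.0,
    seed: int = 0,
) -> SimulatedPopulation:
    """Polygenic phenotypes at a target heritability.

    Additive effects ~ N(0, effect_sd^2) at ``n_qtl`` loci (``"all"`` for
    a fully polygenic trait matching the G-BLUP assumptions); residual
    variance is ``var(TBV) * (1 - h2) / h2`` computed from the realized
    TBV variance, so the in-sample heritability equals ``h2`` up to
    residual sampling noise. ``h2 = 1`` gives noiseless phenotypes.
    """
    if np.isnan(G.values).any():
        raise ValueError("genotypes contain missing values")
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"h2 must lie in (0, 1], got {h2}")
    rng = np.random.default_rng(seed)
    L = G.n_loci
    if n_qtl == "all":
        qtl = np.arange(L)
    else:
        if not 1 <= int(n_qtl) <= L:
            raise ValueError(f"n_qtl must lie in [1, {L}]")
        qtl = np.sort(rng.choice(L, size=int(n_qtl), replace=False))
    effects = np.zeros(L)
    effects[qtl] = rng.normal(0.0, effect_sd, size=len(qtl))
    tbv = (G.values - 0.5) @ effects
    var_tbv = float(np.var(tbv, ddof=1))
    if var_tbv == 0.0 and h2 < 1.0:
        raise ValueError("realized TBV variance is zero; cannot set residual variance")
    sigma_e2 = var_tbv * (1.0 - h2) / h2 if h2 < 1.0 else 0.0
    resid = (
        rng.normal(0.0, np.sqrt(sigma_e2), size=G.n_individuals)
        if sigma_e2 > 0
        else np.zeros(G.n_individuals)
    )
    phen = mu + tbv + resid
    index = list(G.individual_ids)
    return SimulatedPopulation(
        genotypes=G,
        true_breeding_values=pd.Series(tbv, index=index, name="tbv"),
        marker_effects=pd.Series(effects, index=list(G.locus_ids), name="effect"),
        phenotypes=pd.Series(phen, index=index, name="phenotype"),
        target_h2=h2,
        mu=mu,
        sigma_e2=sigma_e2,
        seed=seed,
    )


def realized_family_h2(pop: SimulatedPopulation) -> dict[str, float]:
    """Design-level heritability per family from the simulation ground truth.

    ``h2_f = var(TBV_f) / (var(TBV_f) + sigma_e2)`` — the analogue of the
    experimental-design heritability a field analysis would estimate for
    each family. Includes a ``"pooled"`` entry over all individuals.
    """
    if pop.true_breeding_values is None or pop.sigma_e2 is None:
        raise ValueError("population has no simulated trait")
    fam_of = pop.genotypes.family_of or {}
    tbv = pop.true_breeding_values
    out: dict[str, float] = {}
    families: dict[str, list[str]] = {}
    for ind, fam in fam_of.items():
        families.setdefault(fam, []).append(ind)
    for fam, ids in families.items():
        v = float(tbv.loc[ids].var(ddof=1)) if len(ids) > 1 else 0.0
        out[fam] = v / (v + pop.sigma_e2) if (v + pop.sigma_e2) > 0 else 1.0
    v_all = float(tbv.var(ddof=1))
    out["pooled"] = v_all / (v_all + pop.sigma_e2) if (v_all + pop.sigma_e2) > 0 else 1.0
    return out


def monte_carlo_reliability(
    K: KinshipMatrix,
    calibration_ids: Sequence[str],
    contrast: np.ndarray,
    lam: float,
    reps: int = 10_000,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> float:
    """Empirical squared correlation between a true and predicted contrast.

    Draws ``u ~ N(0, K)`` and ``e ~ N(0, lam * I)`` (i.e. sigma_g^2 = 1,
    sigma_e^2 = lam), forms phenotypes of the calibration records, solves
    the G-BLUP mixed-model equations in one batched factorization, and
    correlates ``c'u`` with ``c'u_hat`` across replicates. This is the
    defining property of the CD, so it serves as its simulation oracle.
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    c = np.asarray(contrast, dtype=float).ravel()
    if c.shape != (K.n,):
        raise ValueError("contrast must have one weight per model individual")
    calibration_ids = [str(i) for i in calibration_ids]
    rng = np.random.default_rng(seed)
    n, N = len(calibration_ids), K.n
    chol = np.linalg.cholesky(ridged(K.K, ridge))
    U = chol @ rng.standard_normal((N, reps))
    E = np.sqrt(lam) * rng.standard_normal((n, reps))
    Z = incidence(calibration_ids, K.individual_ids)
    Y = Z @ U + E
    X = np.ones((n, 1))
    Kinv = np.linalg.inv(ridged(K.K, ridge))
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * Kinv]])
    rhs = np.vstack([X.T @ Y, Z.T @ Y])
    sol = np.linalg.solve(C, rhs)
    Uhat = sol[1:, :]
    true = c @ U
    pred = c @ Uhat
    if np.std(true) == 0.0:
        raise ValueError("degenerate contrast variance in the Monte-Carlo draws")
    if np.std(pred) == 0.0:
        return 0.0  # the model carries no information about the contrast
    r = float(np.corrcoef(true, pred)[0, 1])
    return r * r
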