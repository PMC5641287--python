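"""Genotype matrices, marker QC, and the VanRaden genomic relationship matrix.

Genotypes of inbred / doubled-haploid material are held on a 0-1 dosage
scale: 0 and 1 are the two homozygotes for an arbitrarily labelled
reference allele, 0.5 is the heterozygote, and NaN marks a missing call.
With this coding the mean dosage at a locus equals the reference-allele
frequency, and the genomic relationship between individuals i and j is

    K[i, j] = sum_l (G[i, l] - p_l) * (G[j, l] - p_l) / D,
    D       = sum_l p_l * (1 - p_l),

the VanRaden estimator with allele frequencies ``p_l`` taken either from
the genotyped set itself or from an external reference panel.

On-disk formats are plain text: a genotype table (first column the
individual id, header row the locus ids, cells in {0, 0.5, 1, NA}),
VCF v4.x for variant-call input, and TSV for kinship matrices and
threshold-network edge lists.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strings accepted as a missing genotype call in tables
MISSING_TOKENS = ("NA", "", "nan", "NaN")

#: dosages allowed in raw (un-imputed) genotype files
RAW_DOSAGES = (0.0, 0.5, 1.0)


class GenotypeParseError(ValueError):
    """A genotype file contains a malformed or out-of-range cell."""


@dataclass
class GenotypeMatrix:
    """An individuals x loci dosage matrix with optional family labels.

    ``values`` are dosages in [0, 1] (raw calls are exactly 0, 0.5 or 1;
    family-mean imputation introduces fractional dosages) with NaN for
    missing. ``family_of`` maps individual id -> family label for
    structured material such as NAM designs.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    family_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.individual_ids),
            len(self.locus_ids),
        ):
            raise ValueError(
                f"values has shape {self.values.shape}, expected "
                f"({len(self.individual_ids)}, {len(self.locus_ids)})"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("dosages must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row_indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {ind: k for k, ind in enumerate(self.individual_ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given individuals and/or loci, in the given order."""
        rows = (
            np.arange(self.n_individuals)
            if individuals is None
            else self.row_indices(individuals)
        )
        if loci is None:
            cols = np.arange(self.n_loci)
        else:
            lpos = {l: k for k, l in enumerate(self.locus_ids)}
            cols = np.array([lpos[str(l)] for l in loci], dtype=int)
        ids = [self.individual_ids[r] for r in rows]
        fam = None
        if self.family_of is not None:
            fam = {i: self.family_of[i] for i in ids if i in self.family_of}
        return GenotypeMatrix(
            individual_ids=ids,
            locus_ids=[self.locus_ids[c] for c in cols],
            values=self.values[np.ix_(rows, cols)].copy(),
            family_of=fam,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.locus_ids
        )


@dataclass
class AlleleFrequencies:
    """Per-locus reference-allele frequencies and the set they came from."""

    locus_ids: list[str]
    p: np.ndarray
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.locus_ids),):
            raise ValueError("p must have one entry per locus")
        if np.isnan(self.p).any() or self.p.min() < 0.0 or self.p.max() > 1.0:
            raise ValueError("allele frequencies must lie in [0, 1]")

    def aligned_to(self, locus_ids: Sequence[str]) -> np.ndarray:
        """Return frequencies reordered to ``locus_ids`` (must all be covered)."""
        pos = {l: k for k, l in enumerate(self.locus_ids)}
        missing = [l for l in locus_ids if str(l) not in pos]
        if missing:
            raise ValueError(f"frequencies missing for loci: {missing[:5]}")
        return self.p[[pos[str(l)] for l in locus_ids]]


@dataclass
class KinshipMatrix:
    """A symmetric genomic relationship matrix over an ordered individual set."""

    individual_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.individual_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"K has shape {self.K.shape}, expected ({n}, {n})")
        if n and np.abs(self.K - self.K.T).max() > 1e-12:
            raise ValueError("K is not symmetric (beyond 1e-12)")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        pos = {ind: k for k, ind in enumerate(self.individual_ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = self.indices(ids)
        return KinshipMatrix([str(i) for i in ids], self.K[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# input / output
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "table") -> GenotypeMatrix:
    """Read genotypes from a delimited table or a VCF file.

    Table dialect: UTF-8, tab- or comma-delimited (sniffed), first column
    the individual id, header row the locus ids, cells in
    {0, 0.5, 1, NA/empty}. VCF: biallelic records only; the diploid GT is
    converted to ALT-allele dosage / 2 (0/0 -> 0, 0/1 -> 0.5, 1/1 -> 1,
    ./. -> missing), so the "reference" allele of the dosage coding is the
    VCF ALT allele — allele-frequency sources must use the same labelling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _read_table(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(
        path, sep=None, engine="python", index_col=0, dtype=str,
        keep_default_na=False,
    )
    individual_ids = [str(i) for i in df.index]
    locus_ids = [str(c) for c in df.columns]
    if len(set(individual_ids)) != len(individual_ids):
        raise GenotypeParseError(f"{path}: duplicate individual ids")
    if len(set(locus_ids)) != len(locus_ids):
        raise GenotypeParseError(f"{path}: duplicate locus ids")
    raw = df.to_numpy(dtype=str)
    raw = np.char.strip(raw)
    values = np.full(raw.shape, np.nan)
    present = ~np.isin(raw, MISSING_TOKENS)
    try:
        values[present] = raw[present].astype(float)
    except ValueError:
        _locate_bad_cell(raw, present, individual_ids, locus_ids, path)
    bad = present & ~np.isin(values, RAW_DOSAGES)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: invalid genotype {raw[i, j]!r} at individual "
            f"{individual_ids[i]!r}, locus {locus_ids[j]!r} "
            f"(expected 0, 0.5, 1 or NA)"
        )
    return GenotypeMatrix(individual_ids, locus_ids, values)


def _locate_bad_cell(raw, present, individual_ids, locus_ids, path):
    for i, j in np.argwhere(present):
        try:
            float(raw[i, j])
        except ValueError:
            raise GenotypeParseError(
                f"{path}: unparseable genotype {raw[i, j]!r} at individual "
                f"{individual_ids[i]!r}, locus {locus_ids[j]!r}"
            ) from None
    raise GenotypeParseError(f"{path}: unparseable genotype cell")  # pragma: no cover


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS} "
                f"(ALT={','.join(var.ALT)}); only biallelic records are supported"
            )
        locus_ids.append(
            var.ID if var.ID not in (None, ".", "") else f"{var.CHROM}:{var.POS}"
        )
        col = np.full(len(samples), np.nan)
        for s, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]  # trailing element is the phase flag
            if any(a < 0 for a in alleles):
                continue
            col[s] = float(np.mean(alleles))  # ALT dosage / ploidy
        columns.append(col)
    vcf.close()
    values = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, locus_ids, values)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the tab-delimited genotype table dialect (NA = missing)."""
    df = G.to_frame()
    df.to_csv(Path(path), sep="\t", na_rep="NA", index_label="id")


def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    pd.DataFrame(K.K, index=K.individual_ids, columns=K.individual_ids).to_csv(
        Path(path), sep="\t", index_label="id"
    )


def read_kinship(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    M = df.to_numpy(dtype=float)
    return KinshipMatrix([str(i) for i in df.index], (M + M.T) / 2.0)


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (individual_id, family) TSV into a mapping."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_family_table(family_of: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"individual_id": list(family_of), "family": list(family_of.values())}
    ).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele frequencies, filtering, imputation
# ---------------------------------------------------------------------------


def compute_allele_frequencies(
    G: GenotypeMatrix,
    subset: Sequence[str] | None = None,
    source: str | None = None,
) -> AlleleFrequencies:
    """Reference-allele frequencies as mean non-missing dosage per locus.

    Under the 0/0.5/1 coding the mean dosage over a set of individuals is
    exactly the reference-allele frequency in that set. ``subset`` selects
    the individual set the frequencies are computed on (e.g. an external
    diversity panel carried in the same matrix); default is all
    individuals.
    """
    if subset is None:
        rows = np.arange(G.n_individuals)
        label = source or "all"
    else:
        rows = G.row_indices(subset)
        label = source or "subset"
    vals = G.values[rows]
    n_obs = np.sum(~np.isnan(vals), axis=0)
    empty = n_obs == 0
    if empty.any():
        loci = [G.locus_ids[j] for j in np.flatnonzero(empty)]
        raise ValueError(
            f"loci with no non-missing genotype in the frequency subset: {loci[:10]}"
        )
    with np.errstate(invalid="ignore"):
        p = np.nanmean(vals, axis=0)
    return AlleleFrequencies(list(G.locus_ids), p, source=label)


def filter_markers(
    G: GenotypeMatrix,
    freqs: AlleleFrequencies,
    maf_min: float = 0.01,
    max_marker_missing: float = 0.10,
) -> GenotypeMatrix:
    """Drop loci with MAF <= ``maf_min`` (strict >) or too many missing calls."""
    p = freqs.aligned_to(G.locus_ids)
    maf = np.minimum(p, 1.0 - p)
    miss = np.mean(np.isnan(G.values), axis=0)
    keep = (maf > maf_min) & (miss <= max_marker_missing)
    kept = [l for l, k in zip(G.locus_ids, keep) if k]
    logger.info("filter_markers: kept %d of %d loci", len(kept), G.n_loci)
    return G.subset(loci=kept)


def filter_individuals(
    G: GenotypeMatrix,
    max_indiv_missing: float = 0.10,
    require_phenotype: "pd.Series | pd.DataFrame | Iterable[str] | None" = None,
) -> GenotypeMatrix:
    """Drop individuals with too many missing calls or without phenotypes."""
    keep = np.mean(np.isnan(G.values), axis=1) <= max_indiv_missing
    if require_phenotype is not None:
        if isinstance(require_phenotype, pd.DataFrame):
            phenotyped = set(map(str, require_phenotype.iloc[:, 0]))
        elif isinstance(require_phenotype, pd.Series):
            phenotyped = set(map(str, require_phenotype.index))
        else:
            phenotyped = set(map(str, require_phenotype))
        keep &= np.array([i in phenotyped for i in G.individual_ids])
    kept = [i for i, k in zip(G.individual_ids, keep) if k]
    if not kept:
        raise ValueError("no individuals left after filtering")
    logger.info(
        "filter_individuals: kept %d of %d individuals", len(kept), G.n_individuals
    )
    return G.subset(individuals=kept)


def impute_missing(
    G: GenotypeMatrix, group_of: Mapping[str, str] | None = None
) -> GenotypeMatrix:
    """Replace missing calls by the mean dosage within the individual's group.

    ``group_of`` defaults to the matrix's own family labels. A (group,
    locus) pair with no observed call falls back to the global locus mean
    so that the operator is total; a locus missing everywhere raises.
    """
    group_of = group_of if group_of is not None else G.family_of
    if group_of is None:
        raise ValueError("no group labels available for imputation")
    unlabelled = [i for i in G.individual_ids if i not in group_of]
    if unlabelled:
        raise ValueError(f"individuals without a group label: {unlabelled[:10]}")
    values = G.values.copy()
    if not np.isnan(values).any():
        return GenotypeMatrix(
            list(G.individual_ids), list(G.locus_ids), values,
            family_of=dict(G.family_of) if G.family_of else None,
        )
    n_obs_global = np.sum(~np.isnan(values), axis=0)
    if (n_obs_global == 0).any():
        loci = [G.locus_ids[j] for j in np.flatnonzero(n_obs_global == 0)]
        raise ValueError(f"loci missing in every individual: {loci[:10]}")
    with np.errstate(invalid="ignore"):
        global_mean = np.nanmean(values, axis=0)
    groups = np.array([group_of[i] for i in G.individual_ids])
    for g in np.unique(groups):
        rows = np.flatnonzero(groups == g)
        block = values[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN group column
            gmean = np.nanmean(block, axis=0)
        # degenerate (group, locus) cells: no observed member -> global mean
        gmean = np.where(np.isnan(gmean), global_mean, gmean)
        block[miss] = np.broadcast_to(gmean, block.shape)[miss]
        values[rows] = block
    return GenotypeMatrix(
        list(G.individual_ids), list(G.locus_ids), values,
        family_of=dict(G.family_of) if G.family_of else None,
    )


# ---------------------------------------------------------------------------
# kinship and threshold networks
# ---------------------------------------------------------------------------


def vanraden_kinship(G: GenotypeMatrix, freqs: AlleleFrequencies) -> KinshipMatrix:
    """VanRaden genomic relationship matrix on the 0-1 dosage scale.

    ``K[i, j] = sum_l (G[i,l] - p_l)(G[j,l] - p_l) / D`` with
    ``D = sum_l p_l (1 - p_l)``. Requires a complete (imputed) matrix and
    at least one polymorphic locus in the frequency source (D > 0). When
    the frequencies come from the genotyped set itself, rows of the
    centred matrix sum to zero and so do the rows of K.
    """
    if np.isnan(G.values).any():
        raise ValueError("genotypes contain missing values; impute first")
    p = freqs.aligned_to(G.locus_ids)
    D = float(np.sum(p * (1.0 - p)))
    if D <= 0.0:
        raise ValueError(
            "D = sum p(1-p) is zero: every locus is monomorphic in the "
            f"frequency source {freqs.source!r}"
        )
    M = G.values - p
    K = (M @ M.T) / D
    K = (K + K.T) / 2.0  # remove float round-off asymmetry
    return KinshipMatrix(list(G.individual_ids), K)


def kinship_network_edges(
    K: KinshipMatrix, threshold: float
) -> list[tuple[str, str]]:
    """Unordered pairs (i < j lexicographically) with ``K[i, j] > threshold``."""
    iu, ju = np.triu_indices(K.n, k=1)
    hit = K.K[iu, ju] > threshold
    edges = [
        tuple(sorted((K.individual_ids[a], K.individual_ids[b])))
        for a, b in zip(iu[hit], ju[hit])
    ]
    return sorted(edges)


def write_edges(edges: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["id1", "id2"]).to_csv(
        Path(path), sep="\t", index=False
    )
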