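"""Shared data model and readers/writers for the pipeline's external formats.

Formats handled here: counts TSV (FeatureCounts-style gene x sample table),
sample-metadata TSV, GMT gene-set libraries, and the YAML run configuration.
Gene identifiers are opaque, case-sensitive symbols; no alias mapping is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

GENOTYPE_LEVELS = ("wt", "ko")
TRANSGENE_LEVELS = ("nontg", "tg")

#: a (genotype, transgene) cell of the 2x2 design
Group = tuple[str, str]


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True)
class SampleMeta:
    """One sample's position in the two-factor design."""

    sample_id: str
    genotype: str
    transgene: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_LEVELS:
            raise InputError(
                f"unknown genotype {self.genotype!r} for sample {self.sample_id!r}; "
                f"allowed levels: {list(GENOTYPE_LEVELS)}"
            )
        if self.transgene not in TRANSGENE_LEVELS:
            raise InputError(
                f"unknown transgene {self.transgene!r} for sample {self.sample_id!r}; "
                f"allowed levels: {list(TRANSGENE_LEVELS)}"
            )

    @property
    def group(self) -> Group:
        return (self.genotype, self.transgene)


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative integer read counts.

    Wraps a DataFrame whose index holds gene symbols and whose columns hold
    sample names. Invariants (unique ids, integer non-negative counts) are
    enforced at construction.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise InputError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise InputError(f"duplicate sample id {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise InputError("counts must be numeric")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise InputError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise InputError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        self.counts = df.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class Contrast:
    """A pairwise comparison between two cells of the 2x2 design.

    Fold changes are reported as group_a over group_b.
    """

    name: str
    group_a: Group
    group_b: Group

    def __post_init__(self) -> None:
        for grp in (self.group_a, self.group_b):
            g, t = grp
            if g not in GENOTYPE_LEVELS or t not in TRANSGENE_LEVELS:
                raise InputError(f"contrast {self.name!r}: unknown group {grp!r}")
        if tuple(self.group_a) == tuple(self.group_b):
            raise InputError(f"contrast {self.name!r}: identical groups")


def default_contrasts() -> list[Contrast]:
    """The four pairwise comparisons used throughout the analysis."""
    return [
        Contrast("koTg_vs_wtTg", ("ko", "tg"), ("wt", "tg")),
        Contrast("koNontg_vs_wtNontg", ("ko", "nontg"), ("wt", "nontg")),
        Contrast("wtTg_vs_wtNontg", ("wt", "tg"), ("wt", "nontg")),
        Contrast("koTg_vs_koNontg", ("ko", "tg"), ("ko", "nontg")),
    ]


@dataclass
class AnalysisConfig:
    """Resolved thresholds and knobs of a pipeline run.

    Defaults follow the study design: DEG calling at FDR < 0.05 with
    |log2FC| > 0.1 for enrichment input, clustering-gene selection at
    interaction FDR < 0.2, k scanned over 2..20 with 10 random k-means
    initializations, and reproducibility tolerance 1e-5 on the average
    co-clustered-pair distance.
    """

    deg_fdr: float = 0.05
    deg_abs_log2fc: float = 0.1
    cluster_gene_fdr: float = 0.2
    k_min: int = 2
    k_max: int = 20
    n_init: int = 10
    repro_tol: float = 1e-5
    base_seed: int = 0
    dispersion_prior_df: float = 10.0
    sd_scope: str = "column"
    contrasts: list[Contrast] = field(default_factory=default_contrasts)

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "cluster_gene_fdr", "repro_tol"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InputError(f"{name}={v} outside (0, 1)")
        if self.deg_abs_log2fc < 0:
            raise InputError("deg_abs_log2fc must be >= 0")
        if not (2 <= self.k_min < self.k_max):
            raise InputError(
                f"need 2 <= k_min < k_max, got k_min={self.k_min}, k_max={self.k_max}"
            )
        if self.n_init < 2:
            raise InputError("n_init must be >= 2 (pairwise distances need two runs)")
        if self.dispersion_prior_df < 0:
            raise InputError("dispersion_prior_df must be >= 0")
        if self.sd_scope not in ("column", "global"):
            raise InputError("sd_scope must be 'column' or 'global'")

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dc_fields(self)
            if f.name != "contrasts"
        }
        d["contrasts"] = [
            {"name": c.name, "group_a": list(c.group_a), "group_b": list(c.group_b)}
            for c in self.contrasts
        ]
        return d


@dataclass
class GeneSetLibrary:
    """Named gene sets (GMT library) for over-representation testing."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if len(genes) == 0:
                raise InputError(f"gene set {term!r} is empty")
            if len(set(genes)) != len(genes):
                self.sets[term] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated gene x sample count table.

    First column holds gene ids (header ``gene_id``), remaining columns one
    sample each. Raises :class:`InputError` for duplicate ids and for
    negative or non-integer cells, naming the offending gene/sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise InputError(f"{path}: no sample columns")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().to_numpy().any():
        g, s = np.argwhere(coerced.isna().to_numpy())[0]
        raise InputError(
            f"{path}: non-numeric count at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(coerced)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_meta(path: str | Path) -> list[SampleMeta]:
    """Read the sample-metadata TSV (columns sample_id, genotype, transgene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "transgene"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing metadata columns {sorted(missing)}")
    if len(df) == 0:
        raise InputError(f"{path}: no samples")
    metas = [
        SampleMeta(row.sample_id, row.genotype, row.transgene)
        for row in df.itertuples()
    ]
    seen: set[str] = set()
    for m in metas:
        if m.sample_id in seen:
            raise InputError(f"{path}: duplicate sample id {m.sample_id!r}")
        seen.add(m.sample_id)
    return metas


def write_meta(metas: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "genotype": [m.genotype for m in metas],
            "transgene": [m.transgene for m in metas],
        }
    ).to_csv(path, sep="\t", index=False)


def align_meta(cm: CountMatrix, metas: Sequence[SampleMeta]) -> list[SampleMeta]:
    """Validate the counts/metadata join; return metadata in column order.

    Refuses to proceed unless every count-matrix sample has exactly one
    metadata record and every record a sample.
    """
    by_id = {m.sample_id: m for m in metas}
    missing = [s for s in cm.sample_ids if s not in by_id]
    if missing:
        raise InputError(f"samples without metadata: {missing}")
    extra = [m.sample_id for m in metas if m.sample_id not in set(cm.sample_ids)]
    if extra:
        raise InputError(f"metadata rows without samples: {extra}")
    return [by_id[s] for s in cm.sample_ids]


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT library: term, description, then tab-separated gene symbols."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">= 1 gene ({len(parts)} fields found)"
                )
            term = parts[0]
            if term in sets:
                raise InputError(f"{path}:{lineno}: duplicate term {term!r}")
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if not genes:
                raise InputError(f"{path}:{lineno}: gene set {term!r} is empty")
            sets[term] = genes
    return GeneSetLibrary(sets, source=str(path))


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in library.sets.items():
            fh.write("\t".join([term, ""] + list(genes)) + "\n")


_CONFIG_KEYS = {
    "deg_fdr",
    "deg_abs_log2fc",
    "cluster_gene_fdr",
    "k_min",
    "k_max",
    "n_init",
    "repro_tol",
    "base_seed",
    "dispersion_prior_df",
    "sd_scope",
    "contrasts",
}


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML run configuration; unknown keys are errors.

    An absent or empty file yields the defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise InputError(f"{path}: config must be a key-value mapping")
        raw = dict(loaded)
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    if "contrasts" in raw:
        raw["contrasts"] = [
            Contrast(c["name"], tuple(c["group_a"]), tuple(c["group_b"]))
            for c in raw["contrasts"]
        ]
    return AnalysisConfig(**raw)
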