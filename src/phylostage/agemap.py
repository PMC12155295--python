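"""Gene evolutionary-age (PAI) and sequence-divergence (dN/dS) annotations.

Phylostratigraphy assigns every gene an integer phylostratum — the rank of the
oldest taxonomic node at which homologs of the gene are still detectable.  We
follow the convention in which *higher* values mean *younger* genes; for the
human gene set the meaningful range is 1 (Cellular Organisms) through 14, with
6 = Vertebrata, 7 = Euteleostomi and 9 = Eutheria.  This Phylostratigraphic Age
Index (PAI) is consumed as an input table — homology search and phylostratum
inference happen upstream.

Divergence is quantified per gene as the dN/dS ratio against close relatives.
Because the raw ratio is heavy-tailed, the transcriptome divergence index uses
its decile rank (divergence stratum 1 = the 10% most conserved genes, 10 = the
10% most divergent) rather than the ratio itself; :func:`rank_deciles` performs
that stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

__all__ = [
    "AgeMap",
    "DivergenceMap",
    "DivergenceStrata",
    "load_age_map",
    "load_divergence_map",
    "rank_deciles",
]


@dataclass(frozen=True)
class _StratumMap:
    """Mapping gene id -> integer stratum; base for AgeMap / DivergenceStrata."""

    entries: dict[str, int]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError(f"{type(self).__name__}: no entries")
        for gene, value in self.entries.items():
            if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                raise ValidationError(
                    f"{type(self).__name__}: stratum for {gene!r} is {value!r}, "
                    "expected a positive integer"
                )
            if value < 1:
                raise ValidationError(
                    f"{type(self).__name__}: stratum for {gene!r} is {value} < 1"
                )
        object.__setattr__(
            self, "entries", {g: int(v) for g, v in self.entries.items()}
        )

    @property
    def n_strata(self) -> int:
        """Maximum stratum index present."""
        return max(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def to_series(self) -> pd.Series:
        return pd.Series(self.entries, name="stratum", dtype=int)

    def stratum_vector(self, gene_ids) -> np.ndarray:
        """Strata aligned to ``gene_ids``; genes without annotation get NaN."""
        return np.array(
            [float(self.entries[g]) if g in self.entries else np.nan for g in gene_ids]
        )


@dataclass(frozen=True)
class AgeMap(_StratumMap):
    """Gene -> phylostratum (PAI).  Higher values = evolutionarily younger."""


@dataclass(frozen=True)
class DivergenceStrata(_StratumMap):
    """Gene -> divergence stratum (decile rank of dN/dS, 1..10)."""


@dataclass(frozen=True)
class DivergenceMap:
    """Gene -> raw dN/dS ratio (nonnegative, dimensionless).

    One value per gene: how dN/dS against several reference species is
    aggregated into that value is the data producer's choice and is not
    second-guessed here.
    """

    entries: dict[str, float] = field()

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("DivergenceMap: no entries")
        for gene, value in self.entries.items():
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"DivergenceMap: dN/dS for {gene!r} is {value!r}, "
                    "expected a finite value >= 0"
                )
        object.__setattr__(
            self, "entries", {g: float(v) for g, v in self.entries.items()}
        )

    def __len__(self) -> int:
        return len(self.entries)

    def to_series(self) -> pd.Series:
        return pd.Series(self.entries, name="dnds", dtype=float)


def _read_two_column(path, value_name: str) -> pd.DataFrame:
    """Read a 2-column TSV (gene_id, value); '#' comments ignored, header optional."""
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            skip_blank_lines=True,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: could not read as TSV ({exc})") from exc
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df.columns = ["gene_id", value_name]
    # drop an optional header row, recognized by name (a non-numeric *value*
    # in the first data row must stay visible as a parse error)
    header_names = {"gene", "gene_id", "id"}
    value_names = {"pai", "stratum", "age", "dnds", "dn_ds", "divergence", "value"}
    if (
        str(df.iloc[0, 0]).strip().lower() in header_names
        or str(df.iloc[0, 1]).strip().lower() in value_names
    ):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def load_age_map(path) -> AgeMap:
    """Load a gene -> PAI table from a two-column TSV.

    Exact duplicate rows are deduplicated; the same gene with two different
    PAI values is an error naming the gene.
    """
    df = _read_two_column(path, "pai")
    entries: dict[str, int] = {}
    for row_no, (gene, raw) in enumerate(zip(df["gene_id"], df["pai"]), start=1):
        try:
            value = float(raw)
        except ValueError:
            raise ParseError(f"{path} row {row_no}: non-numeric PAI {raw!r} for {gene!r}")
        if not value.is_integer():
            raise ParseError(f"{path} row {row_no}: non-integer PAI {raw!r} for {gene!r}")
        pai = int(value)
        if pai < 1:
            raise ParseError(f"{path} row {row_no}: PAI {pai} < 1 for {gene!r}")
        if gene in entries and entries[gene] != pai:
            raise ParseError(
                f"{path} row {row_no}: conflicting PAI for {gene!r} "
                f"({entries[gene]} vs {pai})"
            )
        entries[gene] = pai
    return AgeMap(entries)


def load_divergence_map(path) -> DivergenceMap:
    """Load a gene -> dN/dS table from a two-column TSV."""
    df = _read_two_column(path, "dnds")
    entries: dict[str, float] = {}
    for row_no, (gene, raw) in enumerate(zip(df["gene_id"], df["dnds"]), start=1):
        try:
            value = float(raw)
        except ValueError:
            raise ParseError(
                f"{path} row {row_no}: non-numeric dN/dS {raw!r} for {gene!r}"
            )
        if gene in entries and entries[gene] != value:
            raise ParseError(
                f"{path} row {row_no}: conflicting dN/dS for {gene!r} "
                f"({entries[gene]} vs {value})"
            )
        entries[gene] = value
    return DivergenceMap(entries)


def rank_deciles(divergence: DivergenceMap, n_strata: int = 10) -> DivergenceStrata:
    """Stratify genes into balanced dN/dS deciles.

    Genes are sorted by dN/dS ascending, ties broken by lexicographic gene id
    so the stratification is reproducible across runs and platforms.  The
    sorted list is cut into ``n_strata`` contiguous blocks whose sizes differ
    by at most one; when ``n mod n_strata = r > 0`` the extra members go to
    the lowest-index strata, so stratum 1 always holds the most conserved
    genes.  Block *k* becomes divergence stratum *k*.

    Raises
    ------
    ValidationError
        If fewer than ``n_strata`` genes are provided.
    """
    n = len(divergence.entries)
    if n < n_strata:
        raise ValidationError(
            f"rank_deciles: need at least {n_strata} genes, got {n}"
        )
    ordered = sorted(divergence.entries.items(), key=lambda kv: (kv[1], kv[0]))
    base, rem = divmod(n, n_strata)
    entries: dict[str, int] = {}
    pos = 0
    for stratum in range(1, n_strata + 1):
        size = base + (1 if stratum <= rem else 0)
        for gene, _ in ordered[pos : pos + size]:
            entries[gene] = stratum
        pos += size
    return DivergenceStrata(entries)
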