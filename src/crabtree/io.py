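"""Readers and writers for the external formats the pipeline touches.

Differential-expression tables are tab-separated text with at least
``gene_id``, ``fold_change`` and ``p_value`` columns.  Fold changes follow
the signed-ratio convention: a raw expression ratio r >= 1 is stored as r,
and r < 1 as -1/r, so the value is never inside the open interval (-1, 1)
and a threshold of 1.5 reads symmetrically for up- and down-regulation.
Gene sets use the standard GMT dialect (set name, description, gene ids,
tab-separated, one set per line).  Fermenter time courses and off-gas
profiles are plain CSV with an hours-valued time column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _float_repr(x) -> str:
    # shortest digit string that round-trips the double
    return repr(float(x))

DE_COLUMNS = ("gene_id", "fold_change", "p_value")

#: canonical column order for time-course CSVs; extra columns are preserved
TIMECOURSE_COLUMNS = (
    "time",
    "biomass_dw",
    "od600",
    "glucose",
    "ethanol",
    "acetate",
    "glycerol",
    "pyruvate",
    "yeast_cfu",
    "bacteria_cfu",
)

GAS_COLUMNS = (
    "time",
    "y_o2_in",
    "y_o2_out",
    "y_co2_in",
    "y_co2_out",
    "gas_flow",
    "volume",
)


class FormatError(ValueError):
    """A file violates its format contract (missing columns, bad dialect)."""


class RowError(ValueError):
    """One or more rows violate a schema invariant; message lists line numbers."""


def signed_from_ratio(ratio: float) -> float:
    """Convert a raw expression ratio (> 0) to the signed convention."""
    if ratio <= 0:
        raise ValueError(f"expression ratio must be positive, got {ratio}")
    return ratio if ratio >= 1.0 else -1.0 / ratio

def signed_from_log2(log2_fc: float) -> float:
    """Convert a log2 fold change to the signed-ratio convention."""
    return signed_from_ratio(2.0 ** log2_fc)

def ratio_from_signed(signed: float) -> float:
    """Inverse of :func:`signed_from_ratio`."""
    if -1.0 < signed < 1.0:
        raise ValueError(f"signed fold change cannot lie in (-1, 1): {signed}")
    return signed if signed >= 1.0 else -1.0 / signed


def _validate_de_rows(df: pd.DataFrame, path: str) -> None:
    problems: list[str] = []
    # +2: one for the header, one for 0-based indexing
    for idx, row in df.iterrows():
        line = int(idx) + 2
        p = row["p_value"]
        fc = row["fold_change"]
        if not np.isfinite(p) or not (0.0 <= p <= 1.0):
            problems.append(f"line {line}: p_value {p!r} outside [0, 1]")
        if not np.isfinite(fc) or (-1.0 < fc < 1.0):
            problems.append(
                f"line {line}: fold_change {fc!r} invalid under the signed "
                "convention (must satisfy |fc| >= 1)"
            )
    dup_cols = ["gene_id"] + (["replicate_id"] if "replicate_id" in df.columns else [])
    dup = df.duplicated(subset=dup_cols, keep=False)
    if dup.any():
        genes = sorted(df.loc[dup, "gene_id"].unique())
        problems.append(f"duplicate gene ids: {', '.join(map(str, genes[:10]))}")
    if problems:
        raise RowError(f"{path}: " + "; ".join(problems))


def read_de_table(path: str | Path, *, log2: bool = False,
                  condition: str | None = None) -> pd.DataFrame:
    """Read a differential-expression table from tab-separated text.

    Parameters
    ----------
    path
        TSV file with a header naming at least ``gene_id``, ``fold_change``
        and ``p_value``.  An optional ``replicate_id`` column is preserved.
    log2
        If true, ``fold_change`` holds log2 fold changes and is converted to
        the signed-ratio convention on read.
    condition
        Optional condition label stored in ``DataFrame.attrs['condition']``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                         float_precision="round_trip")
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("fold_change", "p_value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = [str(int(i) + 2) for i in df.index[bad][:10]]
            raise RowError(f"{path}: unparsable {col} on line(s) {', '.join(lines)}")
        df[col] = coerced
    if log2:
        df["fold_change"] = df["fold_change"].map(signed_from_log2)
    _validate_de_rows(df, str(path))
    if condition is not None:
        df.attrs["condition"] = condition
    return df


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table as TSV with the canonical column order first."""
    cols = [c for c in DE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, float_format=_float_repr)


@dataclass(frozen=True)
class Pathway:
    """A named gene set with an optional curation category."""

    pathway_id: str
    genes: frozenset[str]
    category: str = ""

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwaySet:
    """Ordered collection of pathways; ids unique, file order preserved."""

    pathways: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate pathway ids: {', '.join(dups)}")

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


def read_gmt(path: str | Path) -> PathwaySet:
    """Read gene sets from a GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    gene ids within one set are collapsed with a logged warning.  The GMT
    description field doubles as the category label.
    """
    path = Path(path)
    pathways: list[Pathway] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, category = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d: set %r has duplicate gene ids; collapsed %d -> %d",
                    path, lineno, name, len(genes), len(unique),
                )
            pathways.append(Pathway(name, unique, category))
    return PathwaySet(pathways)


def write_gmt(pathways: PathwaySet, path: str | Path) -> None:
    """Write gene sets as GMT; genes sorted for byte-reproducibility."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.category, *sorted(p.genes)]) + "\n")


def _read_timed_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    t = df["time"].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing cells", path, n_missing)
    df.attrs["n_missing"] = n_missing
    return df


def read_timecourse(path: str | Path) -> pd.DataFrame:
    """Read a fermentation time course (hours, g/L, log10 cfu/mL) from CSV."""
    return _read_timed_csv(path, required=("time",))


def read_gas_profile(path: str | Path) -> pd.DataFrame:
    """Read an off-gas profile (mole fractions, L/h, L) from CSV."""
    df = _read_timed_csv(path, required=GAS_COLUMNS)
    fr = df[["y_o2_in", "y_o2_out", "y_co2_in", "y_co2_out"]].to_numpy(float)
    if np.any((fr < 0) | (fr > 1)):
        raise FormatError(f"{path}: gas mole fractions must lie in [0, 1]")
    return df


def write_timecourse(tc: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TIMECOURSE_COLUMNS if c in tc.columns]
    cols += [c for c in tc.columns if c not in cols]
    tc[cols].to_csv(path, index=False, float_format=_float_repr)


def write_gas_profile(gp: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in GAS_COLUMNS if c in gp.columns]
    cols += [c for c in gp.columns if c not in cols]
    gp[cols].to_csv(path, index=False, float_format=_float_repr)


@dataclass(frozen=True)
class VariantRecord:
    """A called SNP or indel; identity is (contig, position, ref, alt).

    ``source_label`` records where the call came from (a growth condition or
    an assay) and is deliberately excluded from identity so the same variant
    seen in different call sets compares equal.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantRecord):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


def variant_consensus(call_sets: Sequence[Iterable[VariantRecord]],
                      rule: str = "all") -> set[VariantRecord]:
    """Keep only variants present in every call set.

    ``rule="all"`` intersects any number (>= 2) of call sets, the filter used
    for replicate transcriptome calls across growth conditions; ``rule="both"``
    requires exactly two sets, the cross-assay (RNA vs genomic sequencing)
    consensus.  Identity is the full (contig, position, ref, alt) tuple.
    """
    if rule not in ("all", "both"):
        raise ValueError(f"unknown rule {rule!r}; expected 'all' or 'both'")
    sets = [set(s) for s in call_sets]
    if len(sets) < 2:
        raise ValueError("variant_consensus needs at least 2 call sets")
    if rule == "both" and len(sets) != 2:
        raise ValueError(f"rule 'both' requires exactly 2 call sets, got {len(sets)}")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
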