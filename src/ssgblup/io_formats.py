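"""Plain-text I/O for pedigrees, phenotypes, genotypes and evaluations.

On-disk formats
---------------
Pedigree
    CSV with columns ``animal,sire,dam`` (header optional, auto-detected);
    ``0`` encodes an unknown parent.  On load, animals are renumbered to
    consecutive internal IDs ``1..N`` in topological order (parents always
    precede offspring); every matrix in the package is indexed by these
    internal IDs, and the map back to the original IDs is kept on the
    :class:`Pedigree`.
Phenotypes
    CSV with named columns ``animal,value,year,color,age_days,sex_status``
    (plus an optional ``trait`` column); one trait per file.
Genotypes
    SNP text file in the convention common to animal-breeding software:
    one line per animal holding the animal ID, whitespace, then a contiguous
    string of per-marker dosage codes ``0/1/2`` with ``5`` for a missing
    call.  A CSV dosage dialect is accepted behind ``dialect="csv"``.
Evaluations
    TSV with ``#``-prefixed header lines naming method, trait and variance
    components, then columns ``animal  ebv  genotyped``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ssgblup")

UNKNOWN_PARENT = 0
MISSING_DOSAGE = -1  # internal code; 5 on disk

SEX_STATUS_LEVELS = ("male", "female-empty", "female-lactating")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Topologically ordered pedigree with dense internal IDs ``1..N``.

    ``sire[i]`` / ``dam[i]`` give the internal parent IDs of internal animal
    ``i + 1`` (0 = unknown).  Parents always have a smaller internal ID than
    their offspring.  ``original_ids[i]`` is the external ID of internal
    animal ``i + 1``.
    """

    sire: np.ndarray
    dam: np.ndarray
    original_ids: np.ndarray
    # optional simulator metadata (1 = male, 0 = female); not read from disk
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.original_ids = np.asarray(self.original_ids, dtype=object)
        n = self.n_animals
        if len(self.dam) != n or len(self.original_ids) != n:
            raise PedigreeError("pedigree field lengths disagree")
        ids = np.arange(1, n + 1)
        if np.any(self.sire >= ids) or np.any(self.dam >= ids):
            raise PedigreeError("pedigree is not topologically ordered")
        if np.any(self.sire < 0) or np.any(self.dam < 0):
            raise PedigreeError("negative parent ID")

    @property
    def n_animals(self) -> int:
        return len(self.sire)

    def internal_id(self, original_id) -> int:
        """Map one external ID to its internal ID (1-based)."""
        return self._lookup()[str(original_id)]

    def internal_ids(self, original: Sequence) -> np.ndarray:
        table = self._lookup()
        return np.array([table[str(o)] for o in original], dtype=np.int64)

    def _lookup(self) -> dict:
        if not hasattr(self, "_lookup_cache"):
            self._lookup_cache = {
                str(o): i + 1 for i, o in enumerate(self.original_ids)
            }
        return self._lookup_cache

    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)

    def to_dataframe(self) -> pd.DataFrame:
        orig = self.original_ids
        def back(col):
            return [orig[p - 1] if p else "0" for p in col]
        return pd.DataFrame(
            {"animal": list(orig), "sire": back(self.sire), "dam": back(self.dam)}
        )


def _toposort_renumber(records: list[tuple[str, str, str]]) -> Pedigree:
    """Kahn topological sort + dense renumbering of raw (animal, sire, dam).

    Unknown parents are "0".  Parents that never appear as animals are
    auto-inserted as founders (with a warning); duplicate animals and
    ancestry cycles are hard errors.
    """
    seen: set[str] = set()
    for a, _, _ in records:
        if a in seen:
            raise PedigreeError(f"duplicate animal ID {a!r} in pedigree")
        if a == "0":
            raise PedigreeError("animal ID 0 is reserved for unknown parents")
        seen.add(a)

    parents: dict[str, tuple[str, str]] = {}
    order_hint: list[str] = []
    for a, s, d in records:
        parents[a] = (s, d)
        order_hint.append(a)
    undefined = [
        p
        for a, (s, d) in parents.items()
        for p in (s, d)
        if p != "0" and p not in seen
    ]
    for p in dict.fromkeys(undefined):
        logger.warning(
            "parent %s referenced but never defined; inserted as founder", p
        )
        parents[p] = ("0", "0")
        order_hint.insert(0, p)
        seen.add(p)

    # Kahn's algorithm, stable in file order
    n_unresolved = {
        a: sum(1 for p in ps if p != "0") for a, ps in parents.items()
    }
    children: dict[str, list[str]] = {a: [] for a in parents}
    for a, ps in parents.items():
        for p in ps:
            if p != "0":
                children[p].append(a)
    ready = [a for a in order_hint if n_unresolved[a] == 0]
    topo: list[str] = []
    head = 0
    while head < len(ready):
        a = ready[head]
        head += 1
        topo.append(a)
        for c in children[a]:
            n_unresolved[c] -= 1
            if n_unresolved[c] == 0:
                ready.append(c)
    if len(topo) != len(parents):
        on_cycle = sorted(a for a, k in n_unresolved.items() if k > 0)
        raise PedigreeError(
            f"pedigree contains an ancestry cycle involving animal {on_cycle[0]!r}"
        )

    new_id = {a: i + 1 for i, a in enumerate(topo)}
    sire = np.zeros(len(topo), dtype=np.int64)
    dam = np.zeros(len(topo), dtype=np.int64)
    for a in topo:
        s, d = parents[a]
        i = new_id[a] - 1
        sire[i] = new_id[s] if s != "0" else 0
        dam[i] = new_id[d] if d != "0" else 0
    return Pedigree(sire=sire, dam=dam, original_ids=np.array(topo, dtype=object))


def read_pedigree(path, header: str = "auto") -> Pedigree:
    """Read a pedigree CSV and return it topologically sorted and renumbered.

    Parameters
    ----------
    path : path-like
        CSV with columns animal,sire,dam.
    header : {"auto", "yes", "no"}
        Whether the first line is a header.  "auto" treats a first line
        whose fields include non-numeric tokens such as ``animal`` as a
        header.
    """
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip()
    ]
    if not lines:
        logger.warning("empty pedigree file %s", path)
        return Pedigree(
            sire=np.zeros(0, np.int64),
            dam=np.zeros(0, np.int64),
            original_ids=np.array([], dtype=object),
        )
    start = 0
    if header == "yes":
        start = 1
    elif header == "auto":
        first = [f.strip().lower() for f in lines[0].split(",")]
        if "animal" in first or "sire" in first or "dam" in first:
            start = 1
    records = []
    for k, ln in enumerate(lines[start:], start=start + 1):
        fields = [f.strip() for f in ln.split(",")]
        if len(fields) < 3:
            raise PedigreeError(f"line {k}: expected 3 columns, got {len(fields)}")
        records.append((fields[0], fields[1], fields[2]))
    return _toposort_renumber(records)


def write_pedigree(path, pedigree: Pedigree) -> None:
    pedigree.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Repeated phenotype records for one trait.

    ``data`` columns: ``animal`` (internal ID), ``value``, ``year``,
    ``color``, ``age_days``, ``sex_status``.
    """

    data: pd.DataFrame
    trait: str = "trait"

    def __post_init__(self) -> None:
        required = {"animal", "value", "year", "color", "age_days", "sex_status"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["age_days"] <= 0).any():
            raise ValueError("age_days must be positive")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def animals_with_records(self) -> np.ndarray:
        """Sorted internal IDs of animals having at least one record."""
        return np.unique(self.data["animal"].to_numpy(dtype=np.int64))

    def validate_against(self, pedigree: Pedigree) -> None:
        a = self.data["animal"].to_numpy(dtype=np.int64)
        if len(a) and (a.min() < 1 or a.max() > pedigree.n_animals):
            raise ValueError("phenotype record references animal outside pedigree")

    def subset(self, mask) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[mask].reset_index(drop=True), self.trait)


def read_phenotypes(path, pedigree: Pedigree, trait: str | None = None) -> PhenotypeTable:
    df = pd.read_csv(path)
    if trait is None:
        trait = str(df["trait"].iloc[0]) if "trait" in df.columns and len(df) else "trait"
    if "trait" in df.columns:
        traits = df["trait"].unique()
        if len(traits) > 1:
            raise ValueError(f"one trait per table; found {list(traits)}")
        df = df.drop(columns="trait")
    df["animal"] = pedigree.internal_ids(df["animal"].astype(str))
    tab = PhenotypeTable(df, trait=trait)
    tab.validate_against(pedigree)
    return tab


def write_phenotypes(path, table: PhenotypeTable, pedigree: Pedigree) -> None:
    df = table.data.copy()
    df.insert(0, "trait", table.trait)
    df["animal"] = [pedigree.original_ids[a - 1] for a in df["animal"]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix; internal missing code is -1."""

    animal_ids: np.ndarray          # internal pedigree IDs
    dosages: np.ndarray             # int8, entries {0,1,2,-1}
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            self.dosages = self.dosages.reshape(len(self.animal_ids), -1)
        if len(self.animal_ids) != self.dosages.shape[0]:
            raise ValueError("animal_ids length does not match dosage rows")
        if not self.snp_ids:
            self.snp_ids = [f"snp{j + 1}" for j in range(self.dosages.shape[1])]
        if len(self.snp_ids) != self.dosages.shape[1]:
            raise ValueError("snp_ids length does not match dosage columns")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING_DOSAGE

    def subset_animals(self, internal_ids) -> "GenotypeMatrix":
        internal_ids = np.asarray(internal_ids, dtype=np.int64)
        pos = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([pos[a] for a in internal_ids], dtype=np.int64)
        return GenotypeMatrix(internal_ids, self.dosages[idx], list(self.snp_ids))


def read_genotypes(path, pedigree: Pedigree | None = None,
                   dialect: str = "snp") -> GenotypeMatrix:
    """Read a genotype file (SNP-string dialect by default, CSV behind a flag)."""
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
        raw = df.to_numpy()
        bad = ~np.isin(raw, (0, 1, 2, 5))
        if bad.any():
            raise ValueError(f"invalid dosage value {raw[bad][0]!r} in {path}")
        dos = raw.astype(np.int8)
        dos[dos == 5] = MISSING_DOSAGE
        ids = [str(i) for i in df.index]
        snps = [str(c) for c in df.columns]
    elif dialect == "snp":
        ids, rows = [], []
        width = None
        for k, ln in enumerate(path.read_text().splitlines(), start=1):
            if not ln.strip():
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"line {k}: expected 'ID dosage-string'")
            ident, s = parts
            if width is None:
                width = len(s)
            elif len(s) != width:
                raise ValueError(
                    f"line {k}: ragged line ({len(s)} markers, expected {width})"
                )
            codes = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
            if not np.isin(codes, (0, 1, 2, 5)).all():
                bad = s[int(np.flatnonzero(~np.isin(codes, (0, 1, 2, 5)))[0])]
                raise ValueError(f"line {k}: invalid dosage character {bad!r}")
            row = codes.astype(np.int8)
            row[row == 5] = MISSING_DOSAGE
            ids.append(ident)
            rows.append(row)
        if not rows:
            logger.warning("empty genotype file %s", path)
            dos = np.zeros((0, 0), dtype=np.int8)
        else:
            dos = np.vstack(rows)
        snps = []
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    if pedigree is not None:
        internal = pedigree.internal_ids(ids)
    else:
        internal = np.arange(1, len(ids) + 1, dtype=np.int64)
    gm = GenotypeMatrix(internal, dos, snps)
    gm._original_ids = list(ids)  # kept for writing without a pedigree
    return gm


def write_genotypes(path, genotypes: GenotypeMatrix,
                    pedigree: Pedigree | None = None) -> None:
    dos = genotypes.dosages.copy()
    dos[dos == MISSING_DOSAGE] = 5
    with open(path, "w") as fh:
        for i, a in enumerate(genotypes.animal_ids):
            name = (
                pedigree.original_ids[a - 1] if pedigree is not None else str(a)
            )
            fh.write(f"{name} {''.join(chr(ord('0') + c) for c in dos[i])}\n")


# ---------------------------------------------------------------------------
# Evaluations
# ---------------------------------------------------------------------------

def write_evaluation(path, result, pedigree: Pedigree,
                     genotyped_ids=None) -> None:
    """Write an evaluation result as TSV with a self-describing header.

    ``result`` must expose ``u`` (breeding values over internal IDs 1..N),
    ``kernel`` and ``components`` attributes (see mixed_model.EvaluationResult).
    """
    genotyped = set(np.asarray(genotyped_ids, dtype=np.int64)) if genotyped_ids is not None else set()
    vc = result.components
    with open(path, "w") as fh:
        fh.write(f"# method: {result.kernel}\n")
        fh.write(f"# trait: {getattr(result, 'trait', 'trait')}\n")
        fh.write(
            "# components: sigma_u2=%.12g sigma_c2=%.12g sigma_e2=%.12g\n"
            % (vc.sigma_u2, vc.sigma_c2, vc.sigma_e2)
        )
        fh.write("animal\tebv\tgenotyped\n")
        for i, val in enumerate(result.u):
            a = i + 1
            fh.write(
                f"{pedigree.original_ids[i]}\t{val:.12g}\t{int(a in genotyped)}\n"
            )


def read_evaluation(path) -> pd.DataFrame:
    """Read an evaluation TSV back; header metadata is attached in ``attrs``."""
    meta = {}
    with open(path) as fh:
        rows = []
        header = None
        for ln in fh:
            if ln.startswith("#"):
                key, _, val = ln[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif header is None:
                header = ln.strip().split("\t")
            else:
                rows.append(ln.rstrip("\n").split("\t"))
    df = pd.DataFrame(rows, columns=header or ["animal", "ebv", "genotyped"])
    if len(df):
        df["ebv"] = df["ebv"].astype(float)
        df["genotyped"] = df["genotyped"].astype(int)
    df.attrs.update(meta)
    return df


# ---------------------------------------------------------------------------
# Dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Pedigree + one-trait phenotypes + observed genotype subset."""

    pedigree: Pedigree
    phenotypes: PhenotypeTable
    genotypes: GenotypeMatrix | None = None

    @property
    def genotyped_ids(self) -> np.ndarray:
        if self.genotypes is None:
            return np.zeros(0, dtype=np.int64)
        return self.genotypes.animal_ids
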