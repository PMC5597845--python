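"""Pedigree container, TSV dialect I/O, validation, and sibship (family) assignment.

The on-disk dialect is a UTF-8 TSV with one header row and the columns

    individual_id, father_id, mother_id, sex, birth_year, death_year,
    marriage_years, region

Dates are decimal years (e.g. ``1732.54``): church-register ages and all
downstream covariates operate in years, so calendar arithmetic is avoided
entirely.  ``marriage_years`` is a semicolon-separated list of decimal years.
The missing token is ``NA``.  Sex is ``female``/``male``/``unknown``;
unknown-sex individuals are retained (cohort filters may drop them later).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

COLUMNS = [
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "birth_year",
    "death_year",
    "marriage_years",
    "region",
]

MISSING = "NA"
SEXES = ("female", "male", "unknown")


class PedigreeFormatError(ValueError):
    """Raised when a pedigree file does not conform to the TSV dialect."""


class PedigreeValidationError(ValueError):
    """Raised for structurally invalid pedigrees (e.g. duplicate ids)."""


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    birth_year: float = np.nan
    death_year: float = np.nan
    marriage_years: tuple[float, ...] = ()
    region: str | None = None


@dataclass
class Pedigree:
    """A set of individuals with parent links, backed by a DataFrame.

    ``df`` has one row per individual with the dialect columns;
    ``marriage_years`` holds tuples of floats.  ``family_of`` maps
    individual_id -> family_id once :func:`assign_families` has run.
    """

    df: pd.DataFrame
    family_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[IndividualRecord]) -> "Pedigree":
        rows = [
            {
                "individual_id": r.individual_id,
                "father_id": r.father_id,
                "mother_id": r.mother_id,
                "sex": r.sex,
                "birth_year": r.birth_year,
                "death_year": r.death_year,
                "marriage_years": tuple(r.marriage_years),
                "region": r.region,
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(_normalize(df))

    def records(self) -> list[IndividualRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                IndividualRecord(
                    individual_id=row.individual_id,
                    father_id=row.father_id if pd.notna(row.father_id) else None,
                    mother_id=row.mother_id if pd.notna(row.mother_id) else None,
                    sex=row.sex,
                    birth_year=row.birth_year,
                    death_year=row.death_year,
                    marriage_years=tuple(row.marriage_years),
                    region=row.region if pd.notna(row.region) else None,
                )
            )
        return out

    def unresolved_links(self) -> pd.DataFrame:
        """Parent references that do not name an individual in the pedigree."""
        ids = set(self.df["individual_id"])
        rows = []
        for col in ("father_id", "mother_id"):
            ref = self.df[col]
            bad = self.df.loc[ref.notna() & ~ref.isin(ids), ["individual_id", col]]
            for iid, pid in bad.itertuples(index=False):
                rows.append({"individual_id": iid, "link": col, "target": pid})
        return pd.DataFrame(rows, columns=["individual_id", "link", "target"])


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("individual_id", "father_id", "mother_id", "region"):
        df[col] = df[col].astype(object).where(pd.notna(df[col]), None)
    df["individual_id"] = df["individual_id"].astype(str)
    df["sex"] = df["sex"].fillna("unknown")
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce")
    df["death_year"] = pd.to_numeric(df["death_year"], errors="coerce")
    df["marriage_years"] = df["marriage_years"].map(
        lambda v: tuple(v) if isinstance(v, (tuple, list)) else ()
    )
    return df.reset_index(drop=True)


def _parse_marriages(tok: str) -> tuple[float, ...]:
    if tok == MISSING or tok == "":
        return ()
    return tuple(float(t) for t in tok.split(";"))


def read_pedigree(path) -> Pedigree:
    """Read the TSV dialect.

    Unparseable data rows are collected and reported (with 1-based line
    numbers) on the returned pedigree's ``parse_errors`` attribute rather than
    aborting the whole read; a malformed header or duplicate ids abort.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != COLUMNS:
            missing = set(COLUMNS) - set(header)
            raise PedigreeFormatError(
                f"bad header: expected columns {COLUMNS}, got {header}"
                + (f" (missing {sorted(missing)})" if missing else "")
            )
        rows = []
        errors: list[tuple[int, str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(COLUMNS):
                errors.append((lineno, "wrong field count"))
                continue
            d = dict(zip(COLUMNS, parts))
            try:
                rows.append(
                    {
                        "individual_id": d["individual_id"],
                        "father_id": None if d["father_id"] == MISSING else d["father_id"],
                        "mother_id": None if d["mother_id"] == MISSING else d["mother_id"],
                        "sex": d["sex"],
                        "birth_year": np.nan
                        if d["birth_year"] == MISSING
                        else float(d["birth_year"]),
                        "death_year": np.nan
                        if d["death_year"] == MISSING
                        else float(d["death_year"]),
                        "marriage_years": _parse_marriages(d["marriage_years"]),
                        "region": None if d["region"] == MISSING else d["region"],
                    }
                )
            except ValueError as exc:
                errors.append((lineno, str(exc)))
    df = pd.DataFrame(rows, columns=COLUMNS)
    dup = df["individual_id"][df["individual_id"].duplicated()]
    if len(dup):
        raise PedigreeValidationError(
            f"duplicate individual_id values: {sorted(set(dup))[:10]}"
        )
    ped = Pedigree(_normalize(df))
    ped.parse_errors = errors  # type: ignore[attr-defined]
    return ped


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return MISSING
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_pedigree(pedigree: Pedigree, path) -> str:
    """Write the TSV dialect deterministically (rows sorted by individual_id)."""
    df = pedigree.df.sort_values("individual_id", kind="mergesort")
    buf = io.StringIO()
    buf.write("\t".join(COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        marr = ";".join(format(m, ".6g") for m in row.marriage_years) or MISSING
        fields = [
            row.individual_id,
            _fmt(row.father_id),
            _fmt(row.mother_id),
            row.sex,
            _fmt(row.birth_year),
            _fmt(row.death_year),
            marr,
            _fmt(row.region),
        ]
        buf.write("\t".join(fields) + "\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())
    return str(path)


def validate_pedigree(pedigree: Pedigree) -> pd.DataFrame:
    """Check record- and pedigree-level invariants.

    Returns a report DataFrame with columns (individual_id, rule, detail);
    empty for a clean pedigree.  Always returns (never raises).
    """
    df = pedigree.df
    rows: list[dict] = []

    dup = df["individual_id"][df["individual_id"].duplicated()]
    for iid in sorted(set(dup)):
        rows.append({"individual_id": iid, "rule": "duplicate_id", "detail": ""})

    bad_sex = df.loc[~df["sex"].isin(SEXES), "individual_id"]
    for iid in bad_sex:
        rows.append({"individual_id": iid, "rule": "bad_sex", "detail": ""})

    both = df["birth_year"].notna() & df["death_year"].notna()
    for iid in df.loc[both & (df["death_year"] < df["birth_year"]), "individual_id"]:
        rows.append({"individual_id": iid, "rule": "death_before_birth", "detail": ""})

    for row in df.itertuples(index=False):
        if np.isfinite(row.birth_year):
            for m in row.marriage_years:
                if m < row.birth_year:
                    rows.append(
                        {
                            "individual_id": row.individual_id,
                            "rule": "marriage_before_birth",
                            "detail": format(m, ".6g"),
                        }
                    )

    for bad in pedigree.unresolved_links().itertuples(index=False):
        rows.append(
            {
                "individual_id": bad.individual_id,
                "rule": "unresolved_parent",
                "detail": f"{bad.link}={bad.target}",
            }
        )

    # ancestry cycles: follow parent links; any individual on a cycle is flagged
    parent: dict[str, tuple[str | None, str | None]] = {
        r.individual_id: (r.father_id, r.mother_id) for r in df.itertuples(index=False)
    }
    ids = set(parent)
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def on_cycle(start: str) -> bool:
        stack = [(start, iter([p for p in parent[start] if p in ids]))]
        state[start] = 0
        found = False
        while stack:
            node, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                state[node] = 1
                stack.pop()
                continue
            if state.get(nxt) == 0:
                found = True
            elif nxt not in state:
                state[nxt] = 0
                stack.append((nxt, iter([p for p in parent[nxt] if p in ids])))
        return found

    for iid in parent:
        if iid not in state and on_cycle(iid):
            rows.append({"individual_id": iid, "rule": "ancestry_cycle", "detail": ""})

    return pd.DataFrame(rows, columns=["individual_id", "rule", "detail"])


def assign_families(
    pedigree: Pedigree, mode: str = "couple"
) -> Pedigree | tuple[Mapping[str, str], Mapping[str, str]]:
    """Assign each individual to a sibship.

    mode="couple" (default): one family per (father_id, mother_id) pair, so
    full siblings — and only full siblings — share a family; individuals with
    a missing parent get singleton families.  Returns the pedigree with
    ``family_of`` populated and a ``family_id`` column added.

    mode="per_parent": returns ``(father_group_of, mother_group_of)`` maps in
    which half-siblings through the shared parent are co-grouped (the
    separate-group-per-parent robustness design).
    """
    df = pedigree.df
    fa = df["father_id"]
    mo = df["mother_id"]
    if mode == "per_parent":
        def group(parents: pd.Series, tag: str) -> dict[str, str]:
            out = {}
            for iid, p in zip(df["individual_id"], parents):
                out[iid] = f"{tag}:{p}" if p is not None else f"solo:{iid}"
            return out

        return group(fa, "fa"), group(mo, "mo")
    if mode != "couple":
        raise ValueError(f"unknown family-assignment mode: {mode!r}")

    fam = []
    for iid, f, m in zip(df["individual_id"], fa, mo):
        if f is not None and m is not None:
            fam.append(f"fam:{f}|{m}")
        else:
            fam.append(f"solo:{iid}")
    pedigree.df = df.assign(family_id=fam)
    pedigree.family_of = dict(zip(df["individual_id"], fam))
    return pedigree
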