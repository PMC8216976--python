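"""Readers and writers for the delimited text formats of the pipeline.

All inputs are comma- or tab-delimited text with a header row.  Pair
tables are accepted in two shapes:

* aggregated (canonical for fixtures): one row per sex combination with
  columns ``association_type, species, tide_phase, combination, count``.
  A row with ``combination = N`` declares the table total; when exactly
  one combination row is absent but N is declared, the missing count is
  inferred as N minus the others and flagged on the table.
* long: one row per pair with columns ``association_type, species,
  tide_phase, role1_sex, role2_sex`` (sexes ``M``/``F``).

Validation failures raise :class:`InputValidationError` with the 1-based
file line number of the offending row.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .budget import ScanRecord
from .pairing import COMBINATIONS, GofResult, PairCountTable
from .thermal import TemperatureSeries

__all__ = [
    "InputValidationError",
    "read_pairs",
    "read_scans",
    "read_temps",
    "write_report",
    "write_scans",
    "write_temps",
]


class InputValidationError(ValueError):
    """A malformed input file; the message carries the file line number."""


def _read_delimited(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skip_blank_lines=True, encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise InputValidationError(f"{path}: not valid UTF-8 ({exc})") from None
    except (pd.errors.EmptyDataError, csv.Error):
        raise InputValidationError(
            f"{path}: empty file, expected header with columns {list(required)}"
        ) from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(
            f"{path}: missing required columns {missing} "
            f"(found {list(df.columns)})"
        )
    return df


def _line(idx: int) -> int:
    """File line number of a data row (header is line 1)."""
    return idx + 2


_SEX = {"m": "M", "male": "M", "f": "F", "female": "F"}


def _norm_sex(value: str, path: Path, idx: int) -> str:
    try:
        return _SEX[str(value).strip().lower()]
    except KeyError:
        raise InputValidationError(
            f"{path}:{_line(idx)}: unknown sex {value!r} (expected M or F)"
        ) from None


def read_pairs(path: str | Path) -> list[PairCountTable]:
    """Read pair tables (aggregated or long form), one per
    (association_type, species, tide_phase) group, in file order."""
    path = Path(path)
    probe = _read_delimited(path, ["association_type", "species", "tide_phase"])
    if "combination" in probe.columns and "count" in probe.columns:
        return _pairs_from_aggregated(probe, path)
    if "role1_sex" in probe.columns and "role2_sex" in probe.columns:
        return _pairs_from_long(probe, path)
    raise InputValidationError(
        f"{path}: expected either combination/count or role1_sex/role2_sex columns"
    )


def _group_keys(df: pd.DataFrame) -> list[tuple]:
    seen: list[tuple] = []
    for key in zip(df["association_type"], df["species"], df["tide_phase"]):
        if key not in seen:
            seen.append(key)
    return seen


def _pairs_from_aggregated(df: pd.DataFrame, path: Path) -> list[PairCountTable]:
    tables = []
    for key in _group_keys(df):
        assoc, species, phase = key
        grp = df[
            (df["association_type"] == assoc)
            & (df["species"] == species)
            & (df["tide_phase"] == phase)
        ]
        counts: dict[str, int] = {}
        declared_n: int | None = None
        for idx, row in grp.iterrows():
            combo = str(row["combination"]).strip()
            try:
                value = int(row["count"])
            except (TypeError, ValueError):
                raise InputValidationError(
                    f"{path}:{_line(idx)}: non-integer count {row['count']!r}"
                ) from None
            if value < 0:
                raise InputValidationError(
                    f"{path}:{_line(idx)}: negative count {value}"
                )
            if combo == "N":
                declared_n = value
            elif combo in COMBINATIONS:
                if combo in counts:
                    raise InputValidationError(
                        f"{path}:{_line(idx)}: duplicate combination {combo!r}"
                    )
                counts[combo] = value
            else:
                raise InputValidationError(
                    f"{path}:{_line(idx)}: unknown combination {combo!r}"
                )
        missing = [c for c in COMBINATIONS if c not in counts]
        inferred: tuple[str, ...] = ()
        if missing:
            if declared_n is None or len(missing) > 1:
                raise InputValidationError(
                    f"{path}: table {key}: missing combinations {missing} "
                    "and no declared total to infer from"
                )
            remainder = declared_n - sum(counts.values())
            if remainder < 0:
                raise InputValidationError(
                    f"{path}: table {key}: counts exceed declared total"
                )
            counts[missing[0]] = remainder
            inferred = (missing[0],)
        elif declared_n is not None and declared_n != sum(counts.values()):
            raise InputValidationError(
                f"{path}: table {key}: declared total {declared_n} does not "
                f"match summed counts {sum(counts.values())}"
            )
        tables.append(
            PairCountTable(
                counts=counts,
                association_type=assoc,
                species=species,
                tide_phase=phase,
                inferred=inferred,
            )
        )
    return tables


def _pairs_from_long(df: pd.DataFrame, path: Path) -> list[PairCountTable]:
    tables = []
    for key in _group_keys(df):
        assoc, species, phase = key
        grp = df[
            (df["association_type"] == assoc)
            & (df["species"] == species)
            & (df["tide_phase"] == phase)
        ]
        counts = dict.fromkeys(COMBINATIONS, 0)
        for idx, row in grp.iterrows():
            s1 = _norm_sex(row["role1_sex"], path, idx)
            s2 = _norm_sex(row["role2_sex"], path, idx)
            counts[s1 + s2] += 1
        tables.append(
            PairCountTable(
                counts=counts,
                association_type=assoc,
                species=species,
                tide_phase=phase,
            )
        )
    return tables


def read_scans(path: str | Path) -> list[ScanRecord]:
    """Read individual-scan records; ``behaviors`` is semicolon-separated."""
    path = Path(path)
    df = _read_delimited(
        path, ["timestamp", "quadrat", "species", "individual", "behaviors"]
    )
    records = []
    for idx, row in df.iterrows():
        try:
            ts = pd.Timestamp(row["timestamp"]).to_pydatetime()
        except (TypeError, ValueError):
            raise InputValidationError(
                f"{path}:{_line(idx)}: unparseable timestamp {row['timestamp']!r}"
            ) from None
        behaviors = frozenset(
            b.strip() for b in str(row["behaviors"]).split(";") if b.strip()
        )
        if not behaviors:
            raise InputValidationError(
                f"{path}:{_line(idx)}: empty behavior set"
            )
        records.append(
            ScanRecord(
                timestamp=ts,
                quadrat=str(row["quadrat"]),
                species=str(row["species"]),
                individual=str(row["individual"]),
                behaviors=behaviors,
            )
        )
    if not records:
        raise InputValidationError(f"{path}: no scan records")
    return records


def write_scans(records: Iterable[ScanRecord], path: str | Path) -> Path:
    """Write scan records in the delimited format :func:`read_scans` reads."""
    path = Path(path)
    rows = [
        {
            "timestamp": r.timestamp.isoformat(),
            "quadrat": r.quadrat,
            "species": r.species,
            "individual": r.individual,
            "behaviors": ";".join(sorted(r.behaviors)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_temps(path: str | Path) -> TemperatureSeries:
    """Read an hourly temperature-logger series (ISO 8601 timestamps)."""
    path = Path(path)
    df = _read_delimited(path, ["timestamp", "logger", "site", "temp_c"])
    try:
        df["temp_c"] = df["temp_c"].astype(float)
    except ValueError as exc:
        raise InputValidationError(f"{path}: non-numeric temp_c ({exc})") from None
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except ValueError as exc:
        raise InputValidationError(f"{path}: bad timestamp ({exc})") from None
    return TemperatureSeries(df)


def write_temps(series: TemperatureSeries, path: str | Path) -> Path:
    """Write a temperature series in the format :func:`read_temps` reads."""
    path = Path(path)
    df = series.frame.copy()
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    df.to_csv(path, index=False)
    return path


def write_report(
    results, path: str | Path | None, fmt: str = "tsv"
) -> str:
    """Serialize results (GofResults or a DataFrame) to TSV or JSON.

    Returns the serialized text; also writes it to ``path`` when given.
    Output is bit-stable for fixed inputs and seed.
    """
    if fmt not in ("tsv", "json"):
        raise ValueError("format must be 'tsv' or 'json'")
    if isinstance(results, pd.DataFrame):
        records = results.to_dict(orient="records")
    else:
        results = list(results) if not isinstance(results, GofResult) else [results]
        records = [
            r.to_dict() if isinstance(r, GofResult) else dict(r) for r in results
        ]
    if fmt == "json":
        text = json.dumps(records, indent=2, default=str) + "\n"
    else:
        flat = [
            {
                k: (json.dumps(v, default=str) if isinstance(v, (dict, list)) else v)
                for k, v in rec.items()
            }
            for rec in records
        ]
        text = pd.DataFrame(flat).to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
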