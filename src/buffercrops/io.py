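"""Reading and writing the delimited-text tables and result files.

All tables are UTF-8 delimited text (comma, tab or semicolon, sniffed
from the header line unless overridden).  The supplementary-style inputs
have no fixed published schema, so every reader accepts a column-name
mapping; the defaults below are the package's documented schemas.

Readers validate row by row: rows violating an invariant are dropped and
logged with their row number and reason, so rejected + accepted always
equals the input row count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssocResult
from .binning import BinSeries, BinStat
from .manor import CenturySummary, StabilityTest
from .types import CROPS, ArchContext, ManorRecord, ProxySeries, StationSeries, in_study_window

logger = logging.getLogger(__name__)

#: Default column schemas; override via the ``colmap`` argument.
ARCH_COLUMNS = {
    "site": "site",
    "context": "context",
    "date_early": "date_early",
    "date_late": "date_late",
    "value_kind": "value_kind",  # optional column; defaults to "count"
}
MANOR_COLUMNS = {"manor": "manor", "year": "year", "region": "region"}

_DELIMITERS = (",", "\t", ";")
_FLOAT_FMT = "%.15g"


def sniff_delimiter(path: str | Path, override: str | None = None) -> str:
    """Pick the delimiter among comma/tab/semicolon from the header line."""
    if override is not None:
        return override
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise ValueError(f"could not detect a delimiter in {path}")
    return best


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    sep = sniff_delimiter(path, delimiter)
    return pd.read_csv(path, sep=sep, encoding="utf-8")


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_arch_table(
    path: str | Path,
    delimiter: str | None = None,
    colmap: dict[str, str] | None = None,
) -> list[ArchContext]:
    """Read an archaeobotanical context table.

    Expected columns: site, context, date_early, date_late and the five
    crop columns (rye, oat, millet, buckwheat, hemp).  An optional
    value_kind column marks rows as "count" (default) or "percent".
    Invalid rows are dropped and logged.
    """
    cm = {**ARCH_COLUMNS, **(colmap or {})}
    df = _read_table(path, delimiter)
    _require(df, [cm["site"], cm["context"], cm["date_early"], cm["date_late"], *CROPS], path)
    out: list[ArchContext] = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header
        try:
            early = int(row[cm["date_early"]])
            late = int(row[cm["date_late"]])
        except (TypeError, ValueError):
            logger.warning("%s row %d rejected: unparseable year", path, rowno)
            continue
        kind = str(row.get(cm["value_kind"], "count"))
        if cm["value_kind"] not in df.columns or pd.isna(row.get(cm["value_kind"])):
            kind = "count"
        try:
            ctx = ArchContext(
                site_id=str(row[cm["site"]]),
                context_id=str(row[cm["context"]]),
                date_early=early,
                date_late=late,
                counts={c: (0.0 if pd.isna(row[c]) else float(row[c])) for c in CROPS},
                value_kind=kind,
            )
        except ValueError as exc:
            logger.warning("%s row %d rejected: %s", path, rowno, exc)
            continue
        out.append(ctx)
    logger.info("%s: %d rows read, %d accepted", path, len(df), len(out))
    return out


def read_proxy_series(
    path: str | Path,
    name: str = "",
    units: str = "",
    delimiter: str | None = None,
) -> ProxySeries:
    """Read a two-column (year, value) proxy table; rows with non-numeric
    values are rejected with a log entry, duplicate years are averaged."""
    df = _read_table(path, delimiter)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: proxy table needs (year, value) columns")
    pairs: list[tuple[int, float]] = []
    for i, row in df.iterrows():
        try:
            year = int(row.iloc[0])
            value = float(row.iloc[1])
            if not np.isfinite(value):
                raise ValueError
        except (TypeError, ValueError):
            logger.warning("%s row %d rejected: non-numeric entry", path, i + 2)
            continue
        pairs.append((year, value))
    if not pairs:
        raise ValueError(f"{path}: empty proxy series")
    return ProxySeries.from_pairs(pairs, name=name or Path(path).stem, units=units)


def read_manor_table(
    path: str | Path,
    delimiter: str | None = None,
    colmap: dict[str, str] | None = None,
) -> list[ManorRecord]:
    """Read a manor-inventory table.

    A blank crop cell means the crop was not recorded in that inventory
    (presence flag false); an explicit 0 means recorded as zero.  Records
    outside the 1500-1800 study window are dropped with a log entry.
    """
    cm = {**MANOR_COLUMNS, **(colmap or {})}
    df = _read_table(path, delimiter)
    _require(df, [cm["manor"], cm["year"], *CROPS], path)
    out: list[ManorRecord] = []
    for i, row in df.iterrows():
        rowno = i + 2
        try:
            year = int(row[cm["year"]])
        except (TypeError, ValueError):
            logger.warning("%s row %d rejected: unparseable year", path, rowno)
            continue
        if not in_study_window(year):
            logger.warning(
                "%s row %d out-of-study (year %d outside 1500-1800); excluded",
                path, rowno, year,
            )
            continue
        sown: dict[str, float] = {}
        present: dict[str, bool] = {}
        for c in CROPS:
            if pd.isna(row[c]):
                present[c] = False
            else:
                sown[c] = float(row[c])
                present[c] = True
        region = row.get(cm["region"])
        try:
            rec = ManorRecord(
                manor_id=str(row[cm["manor"]]), year=year, sown=sown,
                present=present,
                region_tag=None if region is None or pd.isna(region) else str(region),
            )
        except ValueError as exc:
            logger.warning("%s row %d rejected: %s", path, rowno, exc)
            continue
        out.append(rec)
    logger.info("%s: %d rows read, %d in-study records", path, len(df), len(out))
    return out


def read_station_tables(
    path: str | Path, region: str | None = None, delimiter: str | None = None
) -> list[StationSeries]:
    """Read a long-format station table: columns station, year, precip_mm
    and (unless ``region`` is given) a region column."""
    df = _read_table(path, delimiter)
    _require(df, ["station", "year", "precip_mm"], path)
    if region is None:
        _require(df, ["region"], path)
    out: list[StationSeries] = []
    for sid, grp in df.groupby("station"):
        data = {}
        for i, row in grp.iterrows():
            try:
                data[int(row["year"])] = float(row["precip_mm"])
            except (TypeError, ValueError):
                logger.warning("%s row %d rejected: non-numeric entry", path, i + 2)
        reg = region if region is not None else str(grp["region"].iloc[0])
        out.append(StationSeries(station_id=str(sid), region=reg, data=data))
    return out


# ---------------------------------------------------------------------------
# writers (and the readers needed for round-trips)

def bin_series_frame(series: BinSeries) -> pd.DataFrame:
    rows = [
        {"bin_start": b.bin_start, "n_contexts": b.n_contexts,
         **{c: b.mean_percent[c] for c in CROPS}}
        for b in series.bins
    ]
    return pd.DataFrame(rows)


def _century_frame(summaries: list[CenturySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"century": s.century, "n_records": s.n_records}
        row.update({f"share_{c}": s.mean_share[c] for c in CROPS})
        row.update({f"mentions_{c}": s.mention_count[c] for c in CROPS})
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results, path: str | Path, format: str = "csv") -> Path:
    """Serialize results (AssocResult/StabilityTest/CenturySummary lists,
    a BinSeries, or a plain DataFrame) to CSV or JSON with >= 15
    significant digits, so a read-back round-trips within 1e-9."""
    path = Path(path)
    if format not in ("csv", "json"):
        raise ValueError("format must be csv|json")

    if isinstance(results, BinSeries):
        df = bin_series_frame(results)
    elif isinstance(results, pd.DataFrame):
        df = results
    elif isinstance(results, list) and results and isinstance(results[0], CenturySummary):
        df = _century_frame(results)
    elif isinstance(results, list) and results and dataclasses.is_dataclass(results[0]):
        df = pd.DataFrame([r.to_dict() for r in results])
    elif isinstance(results, list) and not results:
        df = pd.DataFrame(columns=["empty"])
    elif isinstance(results, dict):
        df = None
    else:
        raise TypeError(f"cannot serialize {type(results)!r}")

    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        if df is None:
            payload = results
        else:
            payload = df.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=float)
    else:
        if df is None:
            df = pd.DataFrame([results])
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_bin_series(path: str | Path, delimiter: str | None = None) -> BinSeries:
    """Read back a BinSeries table written by :func:`write_results`."""
    df = _read_table(path, delimiter)
    _require(df, ["bin_start", "n_contexts", *CROPS], path)
    bins = [
        BinStat(
            bin_start=int(row["bin_start"]),
            mean_percent={c: float(row[c]) for c in CROPS},
            n_contexts=int(row["n_contexts"]),
        )
        for _, row in df.iterrows()
    ]
    return BinSeries(bins=bins)


def write_arch_table(contexts: list[ArchContext], path: str | Path) -> Path:
    rows = [
        {"site": c.site_id, "context": c.context_id, "date_early": c.date_early,
         "date_late": c.date_late, "value_kind": c.value_kind,
         **{crop: c.counts[crop] for crop in CROPS}}
        for c in contexts
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_proxy_series(series: ProxySeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"year": series.years, "value": series.values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def write_manor_table(records: list[ManorRecord], path: str | Path) -> Path:
    rows = []
    for r in records:
        row: dict = {"manor": r.manor_id, "year": r.year, "region": r.region_tag}
        for c in CROPS:
            row[c] = r.sown[c] if r.present[c] else None  # blank = not recorded
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_station_table(stations: list[StationSeries], path: str | Path) -> Path:
    rows = [
        {"station": s.station_id, "region": s.region, "year": y, "precip_mm": v}
        for s in stations
        for y, v in sorted(s.data.items())
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path
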