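"""Loading and persisting model instances.

One table per collection, as either a directory of CSV files
(``tiers.csv``, ``conditions.csv``, ... — UTF-8, comma-separated, header
row required, empty string = null, multi-valued cells joined with ``;``)
or a single JSON bundle keyed by collection name. ``load_model`` and
``write_model`` are exact inverses on valid instances: writing then
reloading yields an equal :class:`~dxnet.model.ModelInstance`, and row
order on disk never matters because instances canonicalize ordering.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Union

import pandas as pd
from pydantic import ValidationError

from .model import (
    CareAssignment,
    Condition,
    ConditionLevel,
    CostInterval,
    Diagnostic,
    DiagnosticIndication,
    EquipmentItem,
    Format,
    Medicine,
    MedicineAssignment,
    ModelInstance,
    Tier,
)


class LoadError(ValueError):
    """Raised when a table cannot be parsed into the relational schema."""


_LIST_SEP = ";"


def _split(cell) -> tuple[str, ...]:
    if cell is None or cell == "":
        return ()
    return tuple(s for s in str(cell).split(_LIST_SEP) if s)


def _join(values) -> str:
    return _LIST_SEP.join(values)


def _opt(cell):
    return None if cell is None or cell == "" else cell


def _bool(cell):
    if cell is None or cell == "":
        return None
    s = str(cell).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {cell!r} as a boolean")


# Per collection: (record class, CSV columns, row -> kwargs, record -> row).
_SCHEMAS: dict[str, tuple[type, tuple[str, ...], Any, Any]] = {
    "tiers": (
        Tier,
        ("id", "name", "rank"),
        lambda r: dict(id=r["id"], name=r["name"], rank=int(r["rank"])),
        lambda t: dict(id=t.id, name=t.name, rank=t.rank),
    ),
    "conditions": (
        Condition,
        ("id", "name", "gbd_term", "source_lists"),
        lambda r: dict(
            id=r["id"], name=r["name"], gbd_term=_opt(r["gbd_term"]), source_lists=_split(r["source_lists"])
        ),
        lambda c: dict(id=c.id, name=c.name, gbd_term=c.gbd_term or "", source_lists=_join(c.source_lists)),
    ),
    "condition_levels": (
        ConditionLevel,
        ("condition_id", "level", "definition"),
        lambda r: dict(condition_id=r["condition_id"], level=r["level"], definition=r["definition"] or ""),
        lambda cl: dict(condition_id=cl.condition_id, level=cl.level, definition=cl.definition),
    ),
    "care_assignments": (
        CareAssignment,
        ("condition_id", "level", "tier_id"),
        lambda r: dict(condition_id=r["condition_id"], level=r["level"], tier_id=r["tier_id"]),
        lambda a: dict(condition_id=a.condition_id, level=a.level, tier_id=a.tier_id),
    ),
    "medicines": (
        Medicine,
        ("id", "name", "eml_note"),
        lambda r: dict(id=r["id"], name=r["name"], eml_note=_opt(r["eml_note"])),
        lambda x: dict(id=x.id, name=x.name, eml_note=x.eml_note or ""),
    ),
    "medicine_assignments": (
        MedicineAssignment,
        ("medicine_id", "condition_id", "level"),
        lambda r: dict(medicine_id=r["medicine_id"], condition_id=r["condition_id"], level=r["level"]),
        lambda a: dict(medicine_id=a.medicine_id, condition_id=a.condition_id, level=a.level),
    ),
    "diagnostics": (
        Diagnostic,
        ("id", "name", "discipline", "modality", "sendout_eligible"),
        lambda r: dict(
            id=r["id"],
            name=r["name"],
            discipline=r["discipline"],
            modality=r["modality"],
            sendout_eligible=_bool(r["sendout_eligible"]),
        ),
        lambda d: dict(
            id=d.id,
            name=d.name,
            discipline=d.discipline,
            modality=d.modality,
            sendout_eligible="true" if d.sendout_eligible else "false",
        ),
    ),
    "indications": (
        DiagnosticIndication,
        ("diagnostic_id", "condition_id", "level", "medicine_id", "indication_class"),
        lambda r: dict(
            diagnostic_id=r["diagnostic_id"],
            condition_id=_opt(r["condition_id"]),
            level=_opt(r["level"]),
            medicine_id=_opt(r["medicine_id"]),
            indication_class=r["indication_class"],
        ),
        lambda i: dict(
            diagnostic_id=i.diagnostic_id,
            condition_id=i.condition_id or "",
            level=i.level or "",
            medicine_id=i.medicine_id or "",
            indication_class=i.indication_class,
        ),
    ),
    "formats": (
        Format,
        ("id", "diagnostic_id", "name", "min_tier_id", "equipment_ids"),
        lambda r: dict(
            id=r["id"],
            diagnostic_id=r["diagnostic_id"],
            name=r["name"],
            min_tier_id=r["min_tier_id"],
            equipment_ids=_split(r["equipment_ids"]),
        ),
        lambda f: dict(
            id=f.id,
            diagnostic_id=f.diagnostic_id,
            name=f.name,
            min_tier_id=f.min_tier_id,
            equipment_ids=_join(f.equipment_ids),
        ),
    ),
    "equipment": (
        EquipmentItem,
        ("id", "name", "cost_low", "cost_high", "workforce_note"),
        lambda r: dict(
            id=r["id"],
            name=r["name"],
            cost=CostInterval(low=float(r["cost_low"]), high=float(r["cost_high"])),
            workforce_note=r["workforce_note"] or "",
        ),
        lambda e: dict(
            id=e.id,
            name=e.name,
            cost_low=e.cost.low,
            cost_high=e.cost.high,
            workforce_note=e.workforce_note,
        ),
    ),
}

COLLECTIONS: tuple[str, ...] = tuple(_SCHEMAS)


def _records_from_rows(name: str, rows: list[dict], source: str) -> list:
    cls, columns, from_row, _ = _SCHEMAS[name]
    out = []
    for i, row in enumerate(rows):
        missing = [c for c in columns if c not in row]
        if missing:
            raise LoadError(f"{source}: row {i + 1}: missing column(s) {missing}")
        try:
            out.append(cls(**from_row(row)))
        except (ValidationError, ValueError, TypeError) as exc:
            raise LoadError(f"{source}: row {i + 1}: {exc}") from exc
    return out


def _rows_from_records(name: str, records) -> list[dict]:
    _, _, _, to_row = _SCHEMAS[name]
    return [to_row(r) for r in records]


def load_model(source: Union[str, Path, Mapping[str, list]]) -> ModelInstance:
    """Load a model from a CSV directory, a JSON bundle file, or in-memory rows.

    ``source`` may be a directory containing one ``<collection>.csv`` per
    collection (missing files mean empty collections), a path to a single
    ``.json`` bundle, or a mapping from collection name to a list of row
    dicts. Parse failures raise :class:`LoadError` naming the file and row.
    """
    if isinstance(source, Mapping):
        tables = {name: list(source.get(name, [])) for name in COLLECTIONS}
        sources = {name: f"<{name}>" for name in COLLECTIONS}
        unknown = set(source) - set(COLLECTIONS)
        if unknown:
            raise LoadError(f"unknown collection(s): {sorted(unknown)}")
    else:
        path = Path(source)
        if path.is_file():
            try:
                bundle = json.loads(path.read_text(encoding="utf-8"))
            except json.JSONDecodeError as exc:
                raise LoadError(f"{path}: not valid JSON: {exc}") from exc
            if not isinstance(bundle, dict):
                raise LoadError(f"{path}: JSON bundle must be an object keyed by collection")
            unknown = set(bundle) - set(COLLECTIONS)
            if unknown:
                raise LoadError(f"{path}: unknown collection(s): {sorted(unknown)}")
            tables = {name: list(bundle.get(name, [])) for name in COLLECTIONS}
            sources = {name: f"{path}#{name}" for name in COLLECTIONS}
        elif path.is_dir():
            tables, sources = {}, {}
            for name in COLLECTIONS:
                f = path / f"{name}.csv"
                sources[name] = str(f)
                if not f.exists():
                    tables[name] = []
                    continue
                try:
                    df = pd.read_csv(f, dtype=str, keep_default_na=False, encoding="utf-8")
                except Exception as exc:
                    raise LoadError(f"{f}: cannot parse CSV: {exc}") from exc
                tables[name] = df.to_dict(orient="records")
        else:
            raise LoadError(f"{path}: no such file or directory")

    kwargs = {
        name: _records_from_rows(name, tables[name], sources[name]) for name in COLLECTIONS
    }
    return ModelInstance(**kwargs)


def write_model(m: ModelInstance, dest: Union[str, Path], format: str = "csv") -> Path:
    """Persist a model as a CSV bundle directory (``format='csv'``) or a
    single JSON bundle file (``format='json'``); returns the written path.

    Output is canonical (sorted rows, fixed column order), so writing the
    same instance twice produces byte-identical files.
    """
    dest = Path(dest)
    if format == "csv":
        dest.mkdir(parents=True, exist_ok=True)
        for name in COLLECTIONS:
            _, columns, _, _ = _SCHEMAS[name]
            rows = _rows_from_records(name, getattr(m, name))
            df = pd.DataFrame(rows, columns=list(columns))
            df.to_csv(dest / f"{name}.csv", index=False, encoding="utf-8")
        return dest
    if format == "json":
        if dest.suffix != ".json":
            dest = dest / "model.json"
        dest.parent.mkdir(parents=True, exist_ok=True)
        bundle = {name: _rows_from_records(name, getattr(m, name)) for name in COLLECTIONS}
        dest.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return dest
    raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")
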