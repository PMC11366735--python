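"""Cohort table reading and writing (CSV and JSON).

The CSV layout is one lesion per row; a ``patient_id`` column groups the
rows of a patient and patient-level fields are repeated on every row.
Empty cells encode absent optional fields (never zero).  Writing is
deterministic: fixed column order, ``repr``-precision floats, so two writes
of the same cohort are byte-identical and read/write round-trips exactly.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import fields as dc_fields
from typing import TextIO

from .schema import Cohort, Lesion, Patient, MORPHOLOGIES, LOCATIONS, VocabularyError


class SchemaError(ValueError):
    """The table does not conform to the documented cohort schema."""


_LESION_COLUMNS = [f.name for f in dc_fields(Lesion)]
_PATIENT_COLUMNS = ["patient_id", "entity", "subtype", "perfusion_available", "swi_available"]
COLUMNS = _PATIENT_COLUMNS + _LESION_COLUMNS

_BOOL_FIELDS = {
    "perfusion_available",
    "swi_available",
    "flair_connected",
    "contrast_enhancing",
    "rcbv_increased",
    "typical_curve",
    "swi_hemorrhage",
    "swi_vascularization",
}
_FLOAT_FIELDS = {
    "diameter_mm",
    "edema_mm",
    "nearest_lesion_distance_mm",
    "adc_ratio_tumor",
    "flair_ratio_tumor",
    "adc_ratio_edema_5mm",
    "adc_ratio_edema_10mm",
    "adc_ratio_edema_20mm",
    "flair_ratio_edema_5mm",
    "flair_ratio_edema_10mm",
    "flair_ratio_edema_20mm",
}


def _encode(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _decode(column: str, cell: str):
    if cell == "":
        return None
    if column in _BOOL_FIELDS:
        if cell not in ("true", "false"):
            raise SchemaError(f"column {column}: boolean cell {cell!r}")
        return cell == "true"
    if column in _FLOAT_FIELDS:
        return float(cell)
    return cell


def write_cohort_table(cohort: Cohort, stream: TextIO, format: str = "csv") -> None:
    """Serialize a cohort to ``stream`` as CSV (lesion rows) or JSON."""
    if format == "csv":
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(COLUMNS)
        for pid, pat in enumerate(cohort.patients):
            head = [
                f"P{pid:04d}",
                pat.entity,
                pat.subtype,
                _encode(pat.perfusion_available),
                _encode(pat.swi_available),
            ]
            for les in pat.lesions:
                writer.writerow(head + [_encode(getattr(les, c)) for c in _LESION_COLUMNS])
    elif format == "json":
        doc = {
            "provenance": cohort.provenance,
            "patients": [
                {
                    "entity": p.entity,
                    "subtype": p.subtype,
                    "perfusion_available": p.perfusion_available,
                    "swi_available": p.swi_available,
                    "lesions": [
                        {c: getattr(les, c) for c in _LESION_COLUMNS}
                        for les in p.lesions
                    ],
                }
                for p in cohort.patients
            ],
        }
        json.dump(doc, stream, indent=1)
        stream.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cohort_table(stream: TextIO, format: str = "csv") -> Cohort:
    """Parse a cohort table written by :func:`write_cohort_table`.

    Raises :class:`SchemaError` when a mandatory column is missing and
    :class:`VocabularyError` when a morphology or location token is outside
    its closed vocabulary.
    """
    if format == "csv":
        reader = csv.reader(stream)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty stream: header row required") from None
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in COLUMNS}
        patients: dict[str, Patient] = {}
        for row in reader:
            if not row:
                continue
            pid = row[idx["patient_id"]]
            if pid not in patients:
                patients[pid] = Patient(
                    entity=row[idx["entity"]],
                    subtype=row[idx["subtype"]],
                    perfusion_available=_decode(
                        "perfusion_available", row[idx["perfusion_available"]]
                    ),
                    swi_available=_decode("swi_available", row[idx["swi_available"]]),
                )
            values = {c: _decode(c, row[idx[c]]) for c in _LESION_COLUMNS}
            _check_vocab(values)
            patients[pid].lesions.append(Lesion(**values))
        return Cohort(list(patients.values()), provenance="file")
    if format == "json":
        doc = json.load(stream)
        pats = []
        for rec in doc["patients"]:
            lesions = []
            for lrec in rec["lesions"]:
                values = {c: lrec.get(c) for c in _LESION_COLUMNS}
                _check_vocab(values)
                lesions.append(Lesion(**values))
            pats.append(
                Patient(
                    entity=rec["entity"],
                    subtype=rec["subtype"],
                    lesions=lesions,
                    perfusion_available=rec["perfusion_available"],
                    swi_available=rec["swi_available"],
                )
            )
        return Cohort(pats, provenance=doc.get("provenance", "file"))
    raise ValueError(f"unknown format {format!r}")


def _check_vocab(values: dict) -> None:
    if values["morphology"] not in MORPHOLOGIES:
        raise VocabularyError(
            f"unknown morphology token {values['morphology']!r}; "
            f"expected one of {MORPHOLOGIES}"
        )
    if values["location"] not in LOCATIONS:
        raise VocabularyError(
            f"unknown location token {values['location']!r}; "
            f"expected one of {LOCATIONS}"
        )


def cohort_to_csv(cohort: Cohort) -> str:
    buf = _io.StringIO()
    write_cohort_table(cohort, buf, "csv")
    return buf.getvalue()


def cohort_from_csv(text: str) -> Cohort:
    return read_cohort_table(_io.StringIO(text), "csv")
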