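"""LNP formulation records and delivery-readout standardization.

Transfection screens report delivery on incompatible scales (luciferase
counts, percent transfected cells, radiant flux ...), so readouts are
only comparable within one publication and one delivery context (e.g.
in vitro HeLa vs in vivo liver).  Records are therefore grouped by
``(publication_id, delivery_context)`` and z-scored within each group,
with a log10 transform applied first when the raw values span enough
orders of magnitude (luminescence-style data).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormulationRecord",
    "StandardizationGroup",
    "Violation",
    "SchemaError",
    "RowParseError",
    "DegenerateGroupError",
    "TransformError",
    "UNREPORTED",
    "read_formulation_table",
    "validate_formulation",
    "standardize_delivery",
]

#: Sentinel distinguishing "field not reported" from "reported as absent"
#: (e.g. a formulation stated to contain no PEG lipid).  Absent is
#: encoded as the empty string, unreported as this sentinel.
UNREPORTED = None

REQUIRED_COLUMNS = (
    "lnp_id",
    "ionizable_lipid_smiles",
    "publication_id",
    "delivery_context",
    "readout_value",
)

RATIO_COLUMNS = ("ionizable", "helper", "cholesterol", "peg", "fifth")


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class RowParseError(ValueError):
    """A row holds an unparseable value; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class DegenerateGroupError(ValueError):
    """A standardization group has zero spread in its raw readouts."""


class TransformError(ValueError):
    """Log transform triggered on a group containing nonpositive values."""


@dataclass(frozen=True)
class FormulationRecord:
    """One LNP formulation: composition, experimental context, readout."""

    lnp_id: str
    ionizable_lipid_smiles: str
    publication_id: str
    delivery_context: str
    readout_value: float
    ionizable_lipid_amine_id: str | None = UNREPORTED
    helper_smiles: str | None = UNREPORTED
    chol_smiles: str | None = UNREPORTED
    peg_smiles: str | None = UNREPORTED
    fifth_smiles: str | None = UNREPORTED
    molar_ratios: Mapping[str, float] = field(default_factory=dict)
    il_to_na_mass_ratio: float | None = UNREPORTED
    cargo: str | None = UNREPORTED
    readout_method: str | None = UNREPORTED
    standardized_readout: float | None = None
    source_row: int | None = None

    @property
    def group_key(self) -> tuple[str, str]:
        return (self.publication_id, self.delivery_context)


@dataclass
class StandardizationGroup:
    """Audit record for one (publication, context) standardization group."""

    group_key: tuple[str, str]
    n: int
    raw_mean: float
    raw_sd: float
    log_applied: bool


@dataclass(frozen=True)
class Violation:
    field_name: str
    rule: str
    value: object


def _opt(raw: object) -> str | None:
    """Tri-state optional text: NaN/missing -> unreported, '' -> absent."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return UNREPORTED
    return str(raw)


def read_formulation_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[FormulationRecord]:
    """Read a formulation CSV into records.

    Parameters
    ----------
    path:
        CSV with one formulation per row.  Required columns:
        ``lnp_id``, ``ionizable_lipid_smiles``, ``publication_id``,
        ``delivery_context``, ``readout_value``.  Molar ratios are read
        from ``<component>_molar_ratio`` columns for the components
        ionizable / helper / cholesterol / peg / fifth.
    schema:
        Optional mapping from the canonical column names above to the
        actual column names in the file.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    RowParseError
        If a ratio or readout cannot be parsed (names the 1-based data
        row).
    """
    df = pd.read_csv(path)
    colmap = dict(schema or {})
    for col in REQUIRED_COLUMNS:
        if colmap.get(col, col) not in df.columns:
            raise SchemaError(f"required column missing: {col!r}")

    records: list[FormulationRecord] = []
    for i, r in enumerate(df.to_dict("records"), start=1):

        def get(col: str) -> object:
            return r.get(colmap.get(col, col))

        ratios: dict[str, float] = {}
        for comp in RATIO_COLUMNS:
            raw = get(f"{comp}_molar_ratio")
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            try:
                ratios[comp] = float(raw)
            except (TypeError, ValueError):
                raise RowParseError(i, f"unparseable molar ratio for {comp!r}: {raw!r}")
        try:
            readout = float(get("readout_value"))
        except (TypeError, ValueError):
            raise RowParseError(i, f"unparseable readout_value: {get('readout_value')!r}")
        if math.isnan(readout):
            raise RowParseError(i, "missing readout_value")

        mass_ratio_raw = get("il_to_na_mass_ratio")
        mass_ratio = None
        if mass_ratio_raw is not None and not (
            isinstance(mass_ratio_raw, float) and math.isnan(mass_ratio_raw)
        ):
            try:
                mass_ratio = float(mass_ratio_raw)
            except (TypeError, ValueError):
                raise RowParseError(i, f"unparseable il_to_na_mass_ratio: {mass_ratio_raw!r}")

        records.append(
            FormulationRecord(
                lnp_id=str(get("lnp_id")),
                ionizable_lipid_smiles=str(get("ionizable_lipid_smiles")),
                publication_id=str(get("publication_id")),
                delivery_context=str(get("delivery_context")),
                readout_value=readout,
                ionizable_lipid_amine_id=_opt(get("ionizable_lipid_amine_id")),
                helper_smiles=_opt(get("helper_smiles")),
                chol_smiles=_opt(get("chol_smiles")),
                peg_smiles=_opt(get("peg_smiles")),
                fifth_smiles=_opt(get("fifth_smiles")),
                molar_ratios=ratios,
                il_to_na_mass_ratio=mass_ratio,
                cargo=_opt(get("cargo")),
                readout_method=_opt(get("readout_method")),
                source_row=i,
            )
        )
    return records


def validate_formulation(
    record: FormulationRecord, tolerance: float = 0.5
) -> list[Violation]:
    """Check record invariants; violations are data, not exceptions.

    ``tolerance`` is the allowed absolute deviation (in percentage
    points) of the stated molar ratios from a 100% total.
    """
    violations: list[Violation] = []
    ratios = dict(record.molar_ratios)
    for comp, val in ratios.items():
        if val < 0:
            violations.append(Violation(f"molar_ratios[{comp}]", "ratio >= 0", val))
    if ratios:
        total = sum(ratios.values())
        if abs(total - 100.0) > tolerance:
            violations.append(
                Violation("molar_ratios", f"sum within {tolerance} of 100", total)
            )
    if record.il_to_na_mass_ratio is not None and record.il_to_na_mass_ratio <= 0:
        violations.append(
            Violation("il_to_na_mass_ratio", "> 0 when present", record.il_to_na_mass_ratio)
        )
    if not record.ionizable_lipid_smiles:
        violations.append(Violation("ionizable_lipid_smiles", "nonempty", ""))
    if not math.isfinite(record.readout_value):
        violations.append(Violation("readout_value", "finite", record.readout_value))
    return violations


def standardize_delivery(
    records: Sequence[FormulationRecord],
    log_trigger_ratio: float = 100.0,
) -> tuple[list[FormulationRecord], list[StandardizationGroup]]:
    """Z-score delivery readouts within (publication, context) groups.

    Within each group the output values have mean 0 and sample
    (n-1 denominator) standard deviation 1.  If the max/min ratio of
    the positive raw values reaches ``log_trigger_ratio`` the group is
    log10-transformed before z-scoring; groups that trigger the log but
    contain nonpositive values raise :class:`TransformError`.

    Returns the records with ``standardized_readout`` filled in (input
    order preserved) and one audit entry per group.

    Raises
    ------
    DegenerateGroupError
        If a group's (possibly log-transformed) values have zero sample
        standard deviation.
    """
    by_group: dict[tuple[str, str], list[int]] = {}
    for idx, rec in enumerate(records):
        by_group.setdefault(rec.group_key, []).append(idx)

    out = list(records)
    audits: list[StandardizationGroup] = []
    for key, idxs in by_group.items():
        raw = np.array([records[i].readout_value for i in idxs], dtype=float)
        if len(raw) < 2:
            raise DegenerateGroupError(
                f"group {key} has fewer than 2 readouts; cannot standardize"
            )
        positive = raw[raw > 0]
        # max/min >= trigger, written multiplicatively to avoid overflow
        log_applied = bool(
            positive.size >= 2
            and positive.max() >= log_trigger_ratio * positive.min()
        )
        vals = raw
        if log_applied:
            if np.any(raw <= 0):
                raise TransformError(
                    f"group {key} triggers log transform but contains "
                    "nonpositive readouts"
                )
            vals = np.log10(raw)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            raise DegenerateGroupError(f"group {key} has constant readouts (sd=0)")
        z = (vals - mean) / sd
        for i, zi in zip(idxs, z):
            out[i] = replace(records[i], standardized_readout=float(zi))
        audits.append(
            StandardizationGroup(
                group_key=key, n=len(raw), raw_mean=mean, raw_sd=sd,
                log_applied=bool(log_applied),
            )
        )
    return out, audits


def records_to_frame(records: Iterable[FormulationRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of records (one row per formulation)."""
    rows = []
    for r in records:
        d = {
            "lnp_id": r.lnp_id,
            "publication_id": r.publication_id,
            "delivery_context": r.delivery_context,
            "ionizable_lipid_smiles": r.ionizable_lipid_smiles,
            "ionizable_lipid_amine_id": r.ionizable_lipid_amine_id,
            "readout_value": r.readout_value,
            "standardized_readout": r.standardized_readout,
        }
        for comp, val in r.molar_ratios.items():
            d[f"{comp}_molar_ratio"] = val
        rows.append(d)
    return pd.DataFrame(rows)


def audits_to_json(audits: Iterable[StandardizationGroup]) -> str:
    """Serialize group audits for the standardization report."""
    payload = [
        {
            "publication_id": a.group_key[0],
            "delivery_context": a.group_key[1],
            "n": a.n,
            "log_applied": a.log_applied,
            "mean": a.raw_mean,
            "sd": a.raw_sd,
        }
        for a in audits
    ]
    return json.dumps(payload, indent=2)
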