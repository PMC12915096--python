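"""Dataset curation: canonicalization, labeling, deduplication and filtering.

Raw fluorescence datasets mix assay-derived activity scores (0–100) with
per-solvent photophysical measurements, and carry duplicates, conflicting
annotations, impossible values and inconsistent replicates.  This module
applies the curation protocol:

* canonicalize structures and drop unparsable SMILES;
* binarize activity scores at a threshold of 20 (score ≥ 20 → fluorescent);
* merge duplicate (structure, condition, label) entries; remove any structure
  annotated with *both* labels;
* exclude measurements lacking solvent information or taken in gaseous
  solvents; enforce quantum yield ≤ 1, wavelengths within 200–1500 nm and
  log10 molar absorptivity ≤ 7;
* within each (structure, solvent, property) replicate group, drop entries
  deviating from the group median by more than the property tolerance
  (5 nm for wavelengths, 0.1 for quantum yield, 0.02 for log10 ε) and average
  the survivors;
* split entries 7:1:2 into train/validation/test.

Every stage reports a :class:`CurationAudit` whose per-rule drop counts sum
to the stage's input count.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem

from .errors import ConfigurationError, DomainError, InvalidStructureError

PROPERTIES = (
    "abs_wavelength",
    "em_wavelength",
    "abs_fwhm",
    "em_fwhm",
    "log10_eps",
    "plqy",
    "lifetime",
)

FLUORESCENT = "fluorescent"
NON_FLUORESCENT = "non-fluorescent"

#: replicate-consistency tolerances; properties absent here (FWHMs, lifetime)
#: get no consistency filter, only averaging
DEFAULT_TOLERANCES = {
    "abs_wavelength": 5.0,
    "em_wavelength": 5.0,
    "plqy": 0.1,
    "log10_eps": 0.02,
}

#: sentinels treated as "no solvent" / gas phase
GASEOUS_SENTINELS = frozenset({"", "gas", "gas phase", "none", "nan", "null"})


@dataclass(frozen=True)
class PhotophysicalMeasurement:
    property: str
    value: float
    solvent_smiles: str | None = None

    def __post_init__(self):
        if self.property not in PROPERTIES:
            raise ConfigurationError(f"unknown property {self.property!r}")


@dataclass
class MoleculeRecord:
    raw_smiles: str
    canonical_smiles: str | None = None
    source: str = ""
    activity_score: float | None = None
    fluorescence_label: str | None = None
    condition: tuple | None = None  # (abs, em) nm test condition, if known
    measurements: list = field(default_factory=list)


@dataclass
class CurationAudit:
    """Per-rule drop counts for one curation stage."""

    stage: str
    n_input: int = 0
    counts: dict = field(default_factory=dict)

    def bump(self, rule: str, k: int = 1):
        self.counts[rule] = self.counts.get(rule, 0) + k

    @property
    def n_dropped(self) -> int:
        return sum(v for k, v in self.counts.items() if k != "retained")

    def as_dict(self) -> dict:
        return {"stage": self.stage, "n_input": self.n_input, **self.counts}


def canonicalize(raw_smiles: str) -> str:
    """Return the canonical SMILES; idempotent, raises on unparsable input."""
    if not isinstance(raw_smiles, str) or not raw_smiles.strip():
        raise InvalidStructureError(str(raw_smiles), "empty input")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise InvalidStructureError(raw_smiles)
    return Chem.MolToSmiles(mol)


def label_from_score(activity_score: float, threshold: float = 20.0) -> str:
    """Binarize a 0–100 assay activity score (score ≥ threshold → fluorescent)."""
    if not 0.0 <= activity_score <= 100.0:
        raise DomainError(f"activity score {activity_score} outside [0, 100]")
    return FLUORESCENT if activity_score >= threshold else NON_FLUORESCENT


def canonicalize_records(records, threshold: float = 20.0):
    """Canonicalize every record, derive missing labels from scores.

    Returns (records, audit); unparsable structures are dropped and counted.
    """
    audit = CurationAudit("canonicalize", n_input=len(records))
    out = []
    for rec in records:
        try:
            can = canonicalize(rec.raw_smiles)
        except InvalidStructureError:
            audit.bump("invalid_smiles")
            continue
        label = rec.fluorescence_label
        if label is None and rec.activity_score is not None:
            label = label_from_score(rec.activity_score, threshold)
        out.append(replace(rec, canonical_smiles=can, fluorescence_label=label))
    audit.bump("retained", len(out))
    return out, audit


def deduplicate_and_resolve(records, task: str = "classification"):
    """Merge duplicate entries and remove conflicting-label structures.

    For classification, entries with identical (canonical SMILES, test
    condition, label) collapse into one; any structure carrying both the
    fluorescent and non-fluorescent label is removed entirely.  For
    regression, duplicates with identical (canonical SMILES,) keys are merged
    by concatenating their measurement lists.
    """
    if task not in ("classification", "regression"):
        raise ConfigurationError(f"unknown task {task!r}")
    audit = CurationAudit("deduplicate", n_input=len(records))
    if not records:
        audit.bump("retained", 0)
        return [], audit

    if task == "classification":
        labels_by_smiles: dict[str, set] = {}
        for rec in records:
            if rec.fluorescence_label is not None:
                labels_by_smiles.setdefault(rec.canonical_smiles, set()).add(
                    rec.fluorescence_label
                )
        conflicted = {s for s, ls in labels_by_smiles.items() if len(ls) > 1}
        groups: dict[tuple, MoleculeRecord] = {}
        for rec in records:
            if rec.canonical_smiles in conflicted:
                audit.bump("conflicting_label")
                continue
            key = (rec.canonical_smiles, rec.condition, rec.fluorescence_label)
            if key in groups:
                audit.bump("duplicates_merged")
                groups[key].measurements.extend(rec.measurements)
            else:
                groups[key] = replace(rec, measurements=list(rec.measurements))
        out = list(groups.values())
    else:
        groups = {}
        for rec in records:
            key = rec.canonical_smiles
            if key in groups:
                audit.bump("duplicates_merged")
                groups[key].measurements = list(groups[key].measurements) + list(
                    rec.measurements
                )
            else:
                groups[key] = replace(rec, measurements=list(rec.measurements))
        out = list(groups.values())
    audit.bump("retained", len(out))
    return out, audit


def _solvent_ok(solvent: str | None) -> bool:
    if solvent is None:
        return False
    if str(solvent).strip().lower() in GASEOUS_SENTINELS:
        return False
    return Chem.MolFromSmiles(str(solvent)) is not None


def _in_range(m: PhotophysicalMeasurement) -> bool:
    v = m.value
    if not np.isfinite(v):
        return False
    if m.property == "plqy":
        return 0.0 <= v <= 1.0
    if m.property in ("abs_wavelength", "em_wavelength"):
        return 200.0 <= v <= 1500.0
    if m.property == "log10_eps":
        return v <= 7.0
    return True


def filter_measurements(records, tolerances=None):
    """Apply solvent/range filters, then replicate outlier removal + averaging.

    Measurement-level audit counts (missing/gaseous solvent, range filter per
    property, replicate inconsistency, replicates merged by averaging,
    retained) sum to the number of input measurements.
    """
    if tolerances is None:
        tolerances = DEFAULT_TOLERANCES
    for prop in tolerances:
        if prop not in PROPERTIES:
            raise ConfigurationError(f"unknown property in tolerances: {prop!r}")

    n_meas = sum(len(r.measurements) for r in records)
    audit = CurationAudit("filter_measurements", n_input=n_meas)

    # group surviving measurements by (smiles, solvent, property)
    groups: dict[tuple, list[float]] = {}
    order: list[tuple] = []
    rec_of: dict[str, MoleculeRecord] = {}
    for rec in records:
        rec_of.setdefault(rec.canonical_smiles, rec)
        for m in rec.measurements:
            if not _solvent_ok(m.solvent_smiles):
                audit.bump("missing_or_gaseous_solvent")
                continue
            if not _in_range(m):
                audit.bump(f"range_{m.property}")
                continue
            key = (rec.canonical_smiles, canonicalize(m.solvent_smiles), m.property)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(float(m.value))

    merged: dict[str, list[PhotophysicalMeasurement]] = {}
    for key in order:
        smiles, solvent, prop = key
        values = groups[key]
        tol = tolerances.get(prop)
        if tol is not None and len(values) > 1:
            med = statistics.median(values)
            keep = [v for v in values if abs(v - med) <= tol]
            audit.bump("replicate_inconsistency", len(values) - len(keep))
            values = keep
        if not values:
            continue
        audit.bump("replicates_averaged", len(values) - 1)
        audit.bump("retained")
        merged.setdefault(smiles, []).append(
            PhotophysicalMeasurement(prop, float(np.mean(values)), solvent)
        )
    audit.counts.setdefault("retained", 0)

    out = []
    for rec in records:
        if rec.canonical_smiles in merged and rec_of[rec.canonical_smiles] is rec:
            out.append(replace(rec, measurements=merged[rec.canonical_smiles]))
        elif not rec.measurements and rec.canonical_smiles not in merged:
            out.append(rec)  # label-only record passes through untouched
    return out, audit


def split_dataset(records, ratios=(0.7, 0.1, 0.2), seed: int = 0):
    """Random 7:1:2 (by default) partition into (train, validation, test).

    Sizes are ``floor(n * r)`` per split with the remainder assigned to
    train; deterministic for a given seed; exhaustive and disjoint.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios):
        raise DomainError(f"negative split ratio in {ratios}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise DomainError(f"split ratios {ratios} do not sum to 1")
    n = len(records)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train : n_train + n_val]]
    test = [records[i] for i in perm[n_train + n_val :]]
    return train, val, test


def curate(records, task: str = "classification", threshold: float = 20.0, tolerances=None):
    """Full curation chain; returns (records, list of per-stage audits)."""
    records, a1 = canonicalize_records(records, threshold)
    records, a2 = deduplicate_and_resolve(records, task)
    records, a3 = filter_measurements(records, tolerances)
    return records, [a1, a2, a3]


# ---------------------------------------------------------------- CSV I/O

def records_from_frame(df: pd.DataFrame):
    """Build records from a long-format table (one entry per row).

    Required column: ``smiles``.  Optional: ``source``, ``score``, ``label``,
    ``solvent_smiles``, ``property``, ``value``, ``abs_query``, ``em_query``.
    """
    if "smiles" not in df.columns:
        raise ConfigurationError("input table must have a 'smiles' column")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def get(col):
            v = d.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        condition = None
        if get("abs_query") is not None and get("em_query") is not None:
            condition = (float(d["abs_query"]), float(d["em_query"]))
        measurements = []
        if get("property") is not None and get("value") is not None:
            solvent = get("solvent_smiles")
            measurements.append(
                PhotophysicalMeasurement(
                    str(d["property"]), float(d["value"]),
                    None if solvent is None else str(solvent),
                )
            )
        records.append(
            MoleculeRecord(
                raw_smiles=str(d["smiles"]),
                source=str(get("source") or ""),
                activity_score=None if get("score") is None else float(d["score"]),
                fluorescence_label=None if get("label") is None else str(d["label"]),
                condition=condition,
                measurements=measurements,
            )
        )
    return records


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        base = {
            "smiles": rec.canonical_smiles or rec.raw_smiles,
            "source": rec.source,
            "score": rec.activity_score,
            "label": rec.fluorescence_label,
            "abs_query": rec.condition[0] if rec.condition else None,
            "em_query": rec.condition[1] if rec.condition else None,
        }
        if rec.measurements:
            for m in rec.measurements:
                rows.append(
                    {**base, "property": m.property, "value": m.value,
                     "solvent_smiles": m.solvent_smiles}
                )
        else:
            rows.append({**base, "property": None, "value": None, "solvent_smiles": None})
    return pd.DataFrame(rows)
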