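"""Cohort container, file I/O and preprocessing for perioperative risk data.

A cohort bundles three modalities per patient:

* a preoperative tabular block (~200 numeric attributes, many missing),
* intraoperative monitoring time series (minutes from series start, value),
* unstructured clinical text (chief complaint, preoperative diagnosis,
  examination conclusions).

Preprocessing follows the conventions of perioperative EHR studies: for each
laboratory attribute the most recent preoperative value is used, walking back
chronologically within a two-week window when the nearest record is null;
numeric attributes are min-max scaled to [0, 1] with statistics estimated on
the training partition only; text is symbol-stripped and whitespace-tokenised.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TEXT_FIELDS = ("chief_complaint", "preop_diagnosis", "exam_conclusions")

ILLNESSES = ("heart", "liver", "renal", "respiratory")


class CohortIntegrityError(ValueError):
    """Raised when an input file violates a cohort invariant (e.g. duplicate ids)."""


class CohortParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass
class PatientRecord:
    """One patient's three modality blocks plus the binary outcome label.

    ``tabular`` maps attribute name -> value (float or None for missing);
    ``tabular_dates`` optionally carries the observation date per attribute.
    ``monitoring`` maps attribute name -> (t_minutes, values) float arrays with
    strictly increasing timestamps. ``text`` maps the three document names to
    raw UTF-8 strings.
    """

    patient_id: str
    label: int
    illness: str = "heart"
    tabular: dict[str, float | None] = field(default_factory=dict)
    tabular_dates: dict[str, _dt.date | None] = field(default_factory=dict)
    text: dict[str, str] = field(default_factory=dict)
    monitoring: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    surgery_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        for attr, (t, v) in self.monitoring.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if t.shape != v.shape:
                raise ValueError(f"monitoring series {attr!r}: t/value length mismatch")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(
                    f"monitoring series {attr!r} of patient {self.patient_id!r}: "
                    "timestamps must be strictly increasing"
                )
            self.monitoring[attr] = (t, v)

    def document_text(self) -> str:
        """Concatenate the named documents in fixed order (complaint, diagnosis, conclusions)."""
        return " ".join(self.text.get(name, "") for name in TEXT_FIELDS)


@dataclass
class Cohort:
    """An ordered collection of :class:`PatientRecord` sharing one tabular schema."""

    records: list[PatientRecord]
    schema: list[str]
    monitoring_attributes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortIntegrityError("duplicate patient_id in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def tabular_frame(self) -> pd.DataFrame:
        """Tabular block as a patients x schema DataFrame (NaN = missing)."""
        data = {
            a: [np.nan if r.tabular.get(a) is None else float(r.tabular[a]) for r in self.records]
            for a in self.schema
        }
        return pd.DataFrame(data, index=[r.patient_id for r in self.records], columns=self.schema)

    def subset(self, indices) -> "Cohort":
        return Cohort(
            records=[self.records[i] for i in indices],
            schema=list(self.schema),
            monitoring_attributes=list(self.monitoring_attributes),
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition protocol (70/20/10 by default)."""

    train_frac: float = 0.70
    val_frac: float = 0.20
    test_frac: float = 0.10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_META_COLS = ("patient_id", "label", "illness", "surgery_date")


def read_cohort(tabular_path, monitoring_path=None, text_path=None) -> Cohort:
    """Assemble a :class:`Cohort` from the three on-disk modality files.

    The tabular file is a CSV whose header defines the schema; reserved columns
    ``patient_id``, ``label``, ``illness`` and ``surgery_date`` carry metadata.
    The monitoring file is long-format CSV ``patient_id,attribute,t_minutes,value``
    (rows may arrive unordered; series are re-sorted by time). The text file is
    JSON-lines with one object per patient. Patients absent from the monitoring
    or text files get empty series / empty documents.
    """
    try:
        tab = pd.read_csv(tabular_path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise CohortParseError(f"cannot parse tabular CSV {tabular_path}: {exc}") from exc
    if "patient_id" not in tab.columns:
        raise CohortParseError(f"{tabular_path}: missing required column 'patient_id'")
    if tab["patient_id"].duplicated().any():
        dupes = tab.loc[tab["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortIntegrityError(f"duplicate patient_id in {tabular_path}: {dupes}")

    schema = [c for c in tab.columns if c not in _META_COLS]

    monitoring: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    mon_attrs: list[str] = []
    if monitoring_path is not None:
        try:
            mon = pd.read_csv(monitoring_path, dtype={"patient_id": str})
        except Exception as exc:  # pragma: no cover
            raise CohortParseError(f"cannot parse monitoring CSV {monitoring_path}: {exc}") from exc
        required = {"patient_id", "attribute", "t_minutes", "value"}
        if not required.issubset(mon.columns):
            raise CohortParseError(
                f"{monitoring_path}: expected columns {sorted(required)}, got {list(mon.columns)}"
            )
        mon_attrs = sorted(mon["attribute"].unique())
        for (pid, attr), g in mon.groupby(["patient_id", "attribute"], sort=False):
            g = g.sort_values("t_minutes")
            monitoring.setdefault(pid, {})[attr] = (
                g["t_minutes"].to_numpy(dtype=float),
                g["value"].to_numpy(dtype=float),
            )

    texts: dict[str, dict[str, str]] = {}
    if text_path is not None:
        with open(text_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CohortParseError(f"{text_path}: malformed JSON on line {lineno}") from exc
                texts[str(obj["patient_id"])] = {k: obj.get(k, "") for k in TEXT_FIELDS}

    records = []
    for _, row in tab.iterrows():
        pid = row["patient_id"]
        surgery = row.get("surgery_date")
        records.append(
            PatientRecord(
                patient_id=pid,
                label=int(row["label"]) if "label" in tab.columns else 0,
                illness=str(row["illness"]) if "illness" in tab.columns else "heart",
                tabular={a: (None if pd.isna(row[a]) else float(row[a])) for a in schema},
                text=texts.get(pid, {}),
                monitoring=monitoring.get(pid, {}),
                surgery_date=_parse_date(surgery),
            )
        )
    return Cohort(records=records, schema=schema, monitoring_attributes=mon_attrs)


def _parse_date(val):
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    if isinstance(val, _dt.date):
        return val
    return _dt.date.fromisoformat(str(val))


def write_cohort(cohort: Cohort, out_dir, manifest_name: str = "cohort.yaml") -> dict:
    """Write a cohort to ``out_dir`` in the three standard files plus a YAML manifest.

    Returns the manifest dict. Round-trip with :func:`read_cohort` preserves
    record count, schema order and all non-missing values exactly.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    tab_path = os.path.join(out_dir, "tabular.csv")
    mon_path = os.path.join(out_dir, "monitoring.csv")
    text_path = os.path.join(out_dir, "text.jsonl")

    rows = []
    for r in cohort.records:
        row = {
            "patient_id": r.patient_id,
            "label": r.label,
            "illness": r.illness,
            "surgery_date": r.surgery_date.isoformat() if r.surgery_date else None,
        }
        row.update({a: r.tabular.get(a) for a in cohort.schema})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_COLS) + list(cohort.schema)).to_csv(tab_path, index=False)

    mon_rows = []
    for r in cohort.records:
        for attr, (t, v) in r.monitoring.items():
            for ti, vi in zip(t, v):
                mon_rows.append((r.patient_id, attr, ti, vi))
    pd.DataFrame(mon_rows, columns=["patient_id", "attribute", "t_minutes", "value"]).to_csv(
        mon_path, index=False
    )

    with open(text_path, "w", encoding="utf-8") as fh:
        for r in cohort.records:
            obj = {"patient_id": r.patient_id}
            obj.update({k: r.text.get(k, "") for k in TEXT_FIELDS})
            fh.write(json.dumps(obj) + "\n")

    manifest = {
        "tabular": "tabular.csv",
        "monitoring": "monitoring.csv",
        "text": "text.jsonl",
        "label_column": "label",
        "illness_column": "illness",
        "surgery_date_column": "surgery_date",
        "n_records": len(cohort),
        "monitoring_attributes": list(cohort.monitoring_attributes),
    }
    with open(os.path.join(out_dir, manifest_name), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_cohort_dir(directory, manifest_name: str = "cohort.yaml") -> Cohort:
    """Read a cohort from a directory written by :func:`write_cohort`."""
    import os

    with open(os.path.join(directory, manifest_name)) as fh:
        manifest = yaml.safe_load(fh)
    return read_cohort(
        os.path.join(directory, manifest["tabular"]),
        os.path.join(directory, manifest["monitoring"]),
        os.path.join(directory, manifest["text"]),
    )


# ---------------------------------------------------------------------------
# Preprocessing rules
# ---------------------------------------------------------------------------


def select_nearest_test(
    observations,
    surgery_date: _dt.date,
    window_days: int = 14,
) -> float | None:
    """Pick the preoperative value for one laboratory attribute.

    ``observations`` is an iterable of ``(date, value)`` with value possibly
    None (a null result). Returns the most recent non-null value dated within
    ``window_days`` before ``surgery_date``; when the nearest record is null,
    walks backward in chronological order inside the window. Returns None when
    no usable value exists.
    """
    cleaned = []
    for d, v in observations:
        if isinstance(d, str):
            d = _dt.date.fromisoformat(d)
        if d > surgery_date:
            raise ValueError(f"observation dated {d} is after surgery date {surgery_date}")
        cleaned.append((d, v))
    for d, v in sorted(cleaned, key=lambda p: p[0], reverse=True):
        if v is None:
            continue
        if (surgery_date - d).days <= window_days:
            return float(v)
        break  # older observations are further outside the window
    return None


@dataclass(frozen=True)
class NormalizationStats:
    """Per-attribute (min, max) learned on the training partition."""

    table: dict[str, tuple[float, float]]

    def transform_value(self, attr: str, x: float | None) -> float | None:
        if x is None:
            return None
        lo, hi = self.table[attr]
        if hi == lo:
            return 0.5
        return float(np.clip((x - lo) / (hi - lo), 0.0, 1.0))


def fit_normalization(frame: pd.DataFrame) -> NormalizationStats:
    """Compute per-attribute min/max on a (training) tabular frame.

    Attributes with no observed value are dropped with a warning.
    """
    table: dict[str, tuple[float, float]] = {}
    for col in frame.columns:
        vals = frame[col].dropna()
        if vals.empty:
            logger.warning("attribute %r has no observed training values; dropped", col)
            continue
        table[col] = (float(vals.min()), float(vals.max()))
    return NormalizationStats(table)


def normalize_tabular(
    cohort: Cohort, stats: NormalizationStats | None = None
) -> tuple[Cohort, NormalizationStats]:
    """Min-max scale the tabular block to [0, 1].

    When ``stats`` is None the scaling statistics are fitted on ``cohort``
    itself (callers pass the *training* cohort, then reuse the returned stats
    for validation/test so no test information leaks into the scaling).
    Missing values stay missing; a constant attribute maps to 0.5.
    """
    if stats is None:
        stats = fit_normalization(cohort.tabular_frame())
    schema = [a for a in cohort.schema if a in stats.table]
    new_records = []
    for r in cohort.records:
        new_tab = {a: stats.transform_value(a, r.tabular.get(a)) for a in schema}
        new_records.append(replace(r, tabular=new_tab))
    return Cohort(new_records, schema=schema, monitoring_attributes=list(cohort.monitoring_attributes)), stats


def normalize_frame(frame: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Apply fitted min-max statistics to a tabular DataFrame (NaN preserved)."""
    out = {}
    for col, (lo, hi) in stats.table.items():
        if col not in frame.columns:
            continue
        x = frame[col].to_numpy(dtype=float)
        if hi == lo:
            scaled = np.where(np.isnan(x), np.nan, 0.5)
        else:
            scaled = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        out[col] = scaled
    return pd.DataFrame(out, index=frame.index, columns=list(stats.table))


_NON_TOKEN = re.compile(r"[^0-9a-z\-]+")


def clean_text(raw: str) -> list[str]:
    """Strip punctuation/symbols and return lowercase whitespace tokens.

    Intra-word hyphens are kept ("t-wave" stays one token); leading/trailing
    hyphens left behind by symbol stripping are trimmed.
    """
    if not raw:
        return []
    lowered = raw.lower()
    cleaned = _NON_TOKEN.sub(" ", lowered)
    tokens = []
    for tok in cleaned.split():
        tok = tok.strip("-")
        if tok:
            tokens.append(tok)
    return tokens


def _largest_remainder(counts: np.ndarray, fracs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Allocate per-class partition counts hitting exact global partition sizes.

    counts: (n_classes,), fracs: (3,), targets: (3,) with targets.sum()==counts.sum().
    Returns an (n_classes, 3) integer allocation with rows summing to counts and
    columns to targets; per-cell deviation from the ideal quota is < 1.
    """
    quotas = np.outer(counts, fracs)
    alloc = np.floor(quotas).astype(int)
    # fix rows: each class must place all its members
    for i in range(len(counts)):
        short = counts[i] - alloc[i].sum()
        rema = quotas[i] - alloc[i]
        for j in np.argsort(-rema)[:short]:
            alloc[i, j] += 1
    # fix columns toward exact global targets by moving single records between
    # partitions, preferring moves that least disturb the class quotas
    col_err = alloc.sum(axis=0) - targets
    while col_err.any():
        src = int(np.argmax(col_err))
        dst = int(np.argmin(col_err))
        over = alloc[:, src] - quotas[:, src]
        order = np.argsort(-over)
        moved = False
        for i in order:
            if alloc[i, src] > 0:
                alloc[i, src] -= 1
                alloc[i, dst] += 1
                moved = True
                break
        if not moved:  # pragma: no cover - defensive
            raise RuntimeError("split allocation failed")
        col_err = alloc.sum(axis=0) - targets
    return alloc


def split_cohort(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort, Cohort]:
    """Partition a cohort into train/validation/test at the spec fractions.

    Sizes are exact: train gets floor(train_frac*n), validation
    floor(val_frac*n), test the remainder. With ``stratified`` the per-class
    allocation follows largest-remainder rounding, so each partition's positive
    count deviates from its ideal share by less than one record. Deterministic
    for a fixed seed.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    n_train = int(np.floor(spec.train_frac * n))
    n_val = int(np.floor(spec.val_frac * n))
    n_test = n - n_train - n_val
    targets = np.array([n_train, n_val, n_test])
    fracs = np.array([spec.train_frac, spec.val_frac, spec.test_frac])
    rng = np.random.default_rng(spec.seed)

    labels = cohort.labels
    parts: list[list[int]] = [[], [], []]
    if spec.stratified:
        classes = sorted(set(labels.tolist()))
        counts = np.array([int((labels == c).sum()) for c in classes])
        alloc = _largest_remainder(counts, fracs, targets)
        for ci, c in enumerate(classes):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            start = 0
            for j in range(3):
                parts[j].extend(idx[start : start + alloc[ci, j]].tolist())
                start += alloc[ci, j]
    else:
        idx = np.arange(n)
        rng.shuffle(idx)
        parts = [idx[:n_train].tolist(), idx[n_train : n_train + n_val].tolist(), idx[n_train + n_val :].tolist()]

    for j, name in enumerate(("train", "validation", "test")):
        if spec.stratified and parts[j] and labels[parts[j]].sum() == 0 and labels.sum() > 0:
            logger.warning("partition %s received zero positive records", name)

    parts = [sorted(p) for p in parts]
    return cohort.subset(parts[0]), cohort.subset(parts[1]), cohort.subset(parts[2])


def select_top_monitoring_attributes(cohort: Cohort, n: int) -> list[str]:
    """Rank monitoring attributes by patient coverage and keep the top ``n``.

    Coverage = number of patients possessing a nonempty series for the
    attribute. Ties break by attribute name, so the result is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: dict[str, int] = {}
    for r in cohort.records:
        for attr, (t, _v) in r.monitoring.items():
            if len(t):
                counts[attr] = counts.get(attr, 0) + 1
    ranked = sorted(counts, key=lambda a: (-counts[a], a))
    if n > len(ranked):
        logger.warning("requested top %d monitoring attributes but only %d exist", n, len(ranked))
    return ranked[:n]
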