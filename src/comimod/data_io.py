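"""Readers/writers for expression tables, GMT gene sets, outcome labels, CoMi
profiles, and fitted-model archives.

All tabular formats are plain tab-separated text.  Expression matrices are
genes x samples with sample ids in the header row and gene ids in the first
column.  Gene sets use the Broad GMT dialect (set_id TAB description TAB
member...).  Labels are either already dichotomized (``sample_id  label`` with
``good``/``bad``) or survival-style (``sample_id  time  event``) to be split at
a follow-up threshold.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: Positive class: good outcome (event-free past the follow-up threshold).
GOOD = 1
#: Negative class: bad outcome (event within the follow-up threshold).
BAD = 0

LABEL_NAMES = {GOOD: "good", BAD: "bad"}
NAME_LABELS = {"good": GOOD, "bad": BAD, "1": GOOD, "0": BAD}

ARCHIVE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path: str | Path,
    na_token: str = "NA",
    transpose: bool = False,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Load a genes x samples expression table.

    Duplicate gene or sample identifiers are an error (offenders listed).
    Cells equal to *na_token* become NaN; genes missing in more than
    *max_missing_fraction* of samples are dropped with a warning.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[na_token],
            keep_default_na=False,
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse expression table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns found (malformed header?)")
    if transpose:
        df = df.T
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise DataError(f"{path}: duplicate gene identifiers: {sorted(map(str, dup_genes))}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise DataError(f"{path}: duplicate sample identifiers: {sorted(map(str, dup_samples))}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        bad = []
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            mask = coerced.isna() & df[col].notna()
            bad.extend((str(g), col) for g in df.index[mask][:3])
        raise DataError(f"{path}: non-numeric cells (gene, sample): {bad[:5]}") from exc
    missing_frac = df.isna().mean(axis=1)
    too_missing = missing_frac > max_missing_fraction
    if too_missing.any():
        logger.warning(
            "%s: dropping %d gene(s) missing in > %.0f%% of samples",
            path, int(too_missing.sum()), 100 * max_missing_fraction,
        )
        df = df.loc[~too_missing]
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "gene_id",
                float_format=float_format, na_rep="NA")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets in load order.

    ``sets`` maps set_id -> ordered tuple of unique member ids;
    ``descriptions`` carries the second GMT column.
    """

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id]

    def as_set(self, set_id: str) -> frozenset[str]:
        return frozenset(self.sets[set_id])

    def add(self, set_id: str, members, description: str = "") -> None:
        if set_id in self.sets:
            raise DataError(f"duplicate gene-set id {set_id!r}")
        unique = tuple(dict.fromkeys(members))
        if not unique:
            raise DataError(f"gene set {set_id!r} is empty")
        self.sets[set_id] = unique
        self.descriptions[set_id] = description

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.sets.values():
            out.update(m)
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set_id TAB description TAB member...).

    Duplicate members within one line are collapsed with a warning; a
    duplicate set_id or a line with fewer than three fields is an error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            set_id, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            unique = tuple(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("%s:%d: set %s has duplicate members; collapsed",
                               path, lineno, set_id)
            if set_id in coll:
                raise DataError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            coll.add(set_id, unique, description)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, members in coll.sets.items():
            desc = coll.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# outcome labels


def read_labels(path: str | Path) -> pd.Series:
    """Read dichotomized labels: two columns, sample_id and good/bad."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns sample_id and label")
    cols = [c.lower() for c in df.columns]
    if "time" in cols and "event" in cols:
        raise DataError(
            f"{path}: looks like survival data (time/event); use read_survival + dichotomize_labels"
        )
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DataError(f"{path}: duplicate sample ids in labels")
    raw = df.iloc[:, 1].astype(str).str.strip().str.lower()
    unknown = sorted(set(raw) - set(NAME_LABELS))
    if unknown:
        raise DataError(f"{path}: unknown label values {unknown}; expected good/bad")
    out = pd.Series([NAME_LABELS[v] for v in raw], index=ids, name="label", dtype="int8")
    return out


def write_labels(labels: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, val in labels.items():
            fh.write(f"{sid}\t{LABEL_NAMES[int(val)]}\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read survival-style labels: sample_id, time (years), event (0/1 or true/false)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "event" not in cols:
        raise DataError(f"{path}: expected 'time' and 'event' columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DataError(f"{path}: duplicate sample ids")
    time = pd.to_numeric(df[cols["time"]], errors="raise").astype(float)
    event = df[cols["event"]].map(
        lambda v: str(v).strip().lower() in {"1", "true", "yes", "1.0"}
    )
    out = pd.DataFrame({"time": time.values, "event": event.values}, index=ids)
    return out


def dichotomize_labels(
    survival: pd.DataFrame,
    threshold: float = 5.0,
    censored_to_good: bool = False,
) -> tuple[pd.Series, dict[str, int]]:
    """Split survival records into good/bad outcome at a follow-up threshold.

    An event at time <= threshold is a bad outcome; any sample followed past
    the threshold (with or without a later event) is good.  Samples censored
    before the threshold carry no outcome information and are excluded by
    default (set *censored_to_good* to label them good instead).

    Returns the label series and a report dict with good/bad/excluded counts.
    """
    if threshold <= 0:
        raise DataError("dichotomization threshold must be positive")
    if (survival["time"] < 0).any():
        raise DataError("negative survival times")
    labels: dict[str, int] = {}
    n_excluded = 0
    for sid, row in survival.iterrows():
        t, ev = float(row["time"]), bool(row["event"])
        if t > threshold:
            labels[str(sid)] = GOOD
        elif ev:
            labels[str(sid)] = BAD
        elif censored_to_good:
            labels[str(sid)] = GOOD
        else:
            n_excluded += 1
    if not labels:
        raise DataError("all samples excluded by dichotomization")
    out = pd.Series(labels, name="label", dtype="int8")
    report = {
        "n_good": int((out == GOOD).sum()),
        "n_bad": int((out == BAD).sum()),
        "n_excluded": n_excluded,
    }
    if n_excluded:
        logger.warning("dichotomize_labels: excluded %d censored sample(s) before %.3g years",
                       n_excluded, threshold)
    return out, report


# ---------------------------------------------------------------------------
# CoMi profiles (feature x sample matrices keyed by "miRNA|GO_id")

FEATURE_SEP = "|"


def write_profile(profile: pd.DataFrame, path: str | Path, float_format: str = "%.17g") -> None:
    """Serialize a CoMi profile; feature key column is 'miRNA|GO_id'."""
    flat = profile.copy()
    flat.index = [f"{m}{FEATURE_SEP}{g}" for m, g in profile.index]
    flat.index.name = "feature"
    flat.to_csv(path, sep="\t", float_format=float_format, na_rep="NA")


def read_profile(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df = df.astype(float)
    keys = []
    for key in df.index.astype(str):
        if FEATURE_SEP not in key:
            raise DataError(f"{path}: feature key {key!r} lacks the '{FEATURE_SEP}' separator")
        mirna, gobp = key.split(FEATURE_SEP, 1)
        keys.append((mirna, gobp))
    df.index = pd.MultiIndex.from_tuples(keys, names=["mirna_id", "gobp_id"])
    df.columns = df.columns.astype(str)
    return df


# ---------------------------------------------------------------------------
# model archives


def config_hash(config: dict) -> str:
    """Stable short hash of an effective configuration dict."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def save_model(model, path: str | Path, provenance: dict | None = None) -> None:
    """Serialize an EnsembleModel or FlatClassifierModel to JSON.

    The archive round-trips bit-identically: predictions on any input are
    unchanged after save/load (floats serialized at full precision via repr).
    """
    payload = model.to_dict()
    payload["schema_version"] = ARCHIVE_SCHEMA_VERSION
    prov = dict(model.provenance or {}) if hasattr(model, "provenance") else {}
    if provenance:
        prov.update(provenance)
    payload["provenance"] = prov
    payload["manifest_hash"] = config_hash(prov)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path):
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != ARCHIVE_SCHEMA_VERSION:
        raise DataError(f"{path}: unsupported model schema version {version!r}")
    kind = payload.get("kind")
    if kind == "ensemble":
        from .ensemble import EnsembleModel

        return EnsembleModel.from_dict(payload)
    if kind == "flat":
        from .baselines import FlatClassifierModel

        return FlatClassifierModel.from_dict(payload)
    raise DataError(f"{path}: unknown model kind {kind!r}")
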