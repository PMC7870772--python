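"""Readers and writers for the tidy behavioural CSV schema and reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_behavior", "write_behavior", "BEHAVIOR_COLUMNS"]

BEHAVIOR_COLUMNS = {
    "participant_id": str,
    "group": str,
    "age_years": float,
    "coherence_pct": float,
    "direction": str,
    "choice": str,
    "rt_s": float,
    "is_catch": bool,
    "trial_index": int,
}

_ENUMS = {"direction": {"up", "down"}, "choice": {"up", "down"}}


def write_behavior(dataset: pd.DataFrame, path) -> None:
    """Write the tidy trial table; column order is normalised so that a
    write/read round-trip is lossless."""
    cols = [c for c in BEHAVIOR_COLUMNS if c in dataset.columns]
    extra = [c for c in dataset.columns if c not in cols]
    dataset[cols + extra].to_csv(path, index=False)


def read_behavior(path, rt_unit: str = "s") -> pd.DataFrame:
    """Read and validate a behavioural trial table.

    Schema problems raise ValueError naming the offending columns and the
    first bad rows (1-based line numbers, header = line 1).  ``rt_unit``
    may be 's' or 'ms'; no unit guessing is attempted.
    """
    if rt_unit not in ("s", "ms"):
        raise ValueError(f"rt_unit must be 's' or 'ms', got {rt_unit!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    if len(df) == 0:
        import warnings

        warnings.warn(f"{path}: no data rows")
        return df.astype({c: t for c, t in BEHAVIOR_COLUMNS.items() if c in df})

    errors = []
    out = pd.DataFrame(index=df.index)
    for col, typ in BEHAVIOR_COLUMNS.items():
        raw = df[col]
        if typ in (float, int):
            vals = pd.to_numeric(raw, errors="coerce")
            allow_nan = col == "rt_s"  # missing response
            bad = vals.isna() & raw.notna() if allow_nan else vals.isna()
            bad &= raw.notna() & (raw.str.strip() != "")
            if bad.any():
                lines = (np.nonzero(bad.to_numpy())[0] + 2)[:5].tolist()
                errors.append(f"column {col!r}: unparseable values near lines {lines} "
                              f"(e.g. {raw[bad].iloc[0]!r}); locale decimal commas are not accepted")
            out[col] = vals
        elif typ is bool:
            low = raw.str.strip().str.lower()
            ok = low.isin(["true", "false", "0", "1"])
            if not ok.all():
                lines = (np.nonzero(~ok.to_numpy())[0] + 2)[:5].tolist()
                errors.append(f"column {col!r}: non-boolean values near lines {lines}")
            out[col] = low.isin(["true", "1"])
        else:
            out[col] = raw
            if col in _ENUMS:
                ok = raw.isin(_ENUMS[col]) | raw.isna()
                if not ok.all():
                    bad_vals = sorted(set(raw[~ok].dropna()))[:5]
                    errors.append(f"column {col!r}: invalid values {bad_vals} "
                                  f"(allowed: {sorted(_ENUMS[col])})")
    if errors:
        raise ValueError(f"{path}: schema validation failed:\n  " + "\n  ".join(errors))
    if rt_unit == "ms":
        out["rt_s"] = out["rt_s"] / 1000.0
    for col in df.columns:
        if col not in out.columns:
            if col in ("correct", "is_contaminant"):
                out[col] = df[col].str.strip().str.lower().isin(["true", "1"])
            else:
                out[col] = df[col]
    # numeric passthrough for extra columns where possible
    for col in out.columns:
        if col not in BEHAVIOR_COLUMNS and out[col].dtype == object:
            conv = pd.to_numeric(out[col], errors="coerce")
            if conv.notna().all():
                out[col] = conv
    out["trial_index"] = out["trial_index"].astype(int)
    return out


def write_report(df: pd.DataFrame, path_base) -> None:
    """Serialise a report table as CSV plus JSON."""
    base = Path(path_base)
    df.to_csv(base.with_suffix(".csv"))
    df.reset_index().to_json(base.with_suffix(".json"), orient="records", indent=1)
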