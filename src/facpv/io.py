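"""CSV readers/writers and prevalence-input parsing.

Subject-level data come in two layouts:

* **wide** — one row per subject: ``subject_id, gold, <one 0/1 column per
  modality>``;
* **long** — one row per (subject, modality): ``subject_id, gold, modality,
  result``.

Both are plain RFC-4180 CSV handled by pandas.  Long input is pivoted to wide
at read time; duplicated (subject, modality) pairs, inconsistent gold labels
and missing cells are errors — the analysis requires every subject to be
examined by every modality (complete cases).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import PrevalenceSpec, TestResultsTable

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_prevalence",
    "load_prevalence_config",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_trial_csv(
    path,
    format: str = "wide",
    id_col: str = "subject_id",
    gold_col: str = "gold",
    modality_cols: list[str] | None = None,
) -> TestResultsTable:
    """Read subject-level trial data from CSV.

    Parameters
    ----------
    path : str or path-like
    format : {"wide", "long"}
    id_col, gold_col : str
        Column names for subject identifier and gold standard.
    modality_cols : list of str, optional
        Wide format only: which columns hold test results.  Defaults to all
        columns other than ``id_col`` and ``gold_col``.
    """
    df = _read_csv(path)
    if format == "long":
        df = _pivot_long(df, id_col, gold_col)
        modality_cols = [c for c in df.columns if c not in (id_col, gold_col)]
    elif format != "wide":
        raise ValueError(f"format must be 'wide' or 'long', got {format!r}")

    for col in (id_col, gold_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if modality_cols is None:
        modality_cols = [c for c in df.columns if c not in (id_col, gold_col)]
    if not modality_cols:
        raise ValueError("no modality result columns found")
    missing = [c for c in modality_cols if c not in df.columns]
    if missing:
        raise ValueError(f"modality columns not in file: {missing}")

    sub = df[[id_col, gold_col] + modality_cols]
    if sub.isna().any().any():
        raise ValueError(
            "missing cells: every subject must have a gold label and a result "
            "for every modality (complete-case requirement)"
        )
    return TestResultsTable(
        subject_id=sub[id_col].to_numpy(),
        gold=sub[gold_col].to_numpy(),
        results=sub[modality_cols].to_numpy(),
        modality_labels=list(map(str, modality_cols)),
    )


def _pivot_long(df: pd.DataFrame, id_col: str, gold_col: str) -> pd.DataFrame:
    for col in (id_col, gold_col, "modality", "result"):
        if col not in df.columns:
            raise ValueError(f"long format requires column {col!r}")
    if df.duplicated([id_col, "modality"]).any():
        dup = df[df.duplicated([id_col, "modality"], keep=False)]
        raise ValueError(
            f"duplicate (subject, modality) pairs in long input:\n{dup.head()}"
        )
    gold_per_subject = df.groupby(id_col)[gold_col].nunique()
    if (gold_per_subject > 1).any():
        bad = gold_per_subject[gold_per_subject > 1].index.tolist()
        raise ValueError(f"inconsistent gold labels for subjects {bad}")
    wide = df.pivot(index=id_col, columns="modality", values="result")
    if wide.isna().any().any():
        raise ValueError("missing cells after pivoting long input to wide")
    gold = df.groupby(id_col)[gold_col].first()
    out = wide.reset_index()
    out[gold_col] = gold.loc[out[id_col]].to_numpy()
    cols = [id_col, gold_col] + [c for c in wide.columns]
    out = out[cols]
    out.columns = [id_col, gold_col] + [str(c) for c in wide.columns]
    return out


def write_trial_csv(table: TestResultsTable, path, format: str = "wide") -> None:
    """Write a :class:`TestResultsTable` back to CSV (wide or long)."""
    wide = pd.DataFrame(
        {"subject_id": table.subject_id, "gold": table.gold}
        | {lab: table.results[:, j] for j, lab in enumerate(table.modality_labels)}
    )
    if format == "wide":
        wide.to_csv(path, index=False)
    elif format == "long":
        long = wide.melt(
            id_vars=["subject_id", "gold"], var_name="modality", value_name="result"
        )
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"format must be 'wide' or 'long', got {format!r}")


def read_prevalence(entries) -> PrevalenceSpec:
    """Build a :class:`PrevalenceSpec` from heterogeneous group entries.

    Each entry is one of

    * ``(label, k, m)`` — counts from a prior prevalence study, giving
      ``pi_hat = k/m`` and binomial variance ``pi_hat(1-pi_hat)/m``;
    * ``(label, pi, True)`` or ``(label, pi)`` with ``0 < pi < 1`` float —
      a fixed, known prevalence with variance 0;
    * a dict ``{"label": ..., "k": ..., "m": ...}`` or
      ``{"label": ..., "pi": ..., "fixed": True}``.
    """
    labels, k_, m_, pi_, var_, fix_ = [], [], [], [], [], []
    for entry in entries:
        if isinstance(entry, dict):
            label = entry["label"]
            if "k" in entry:
                entry = (label, entry["k"], entry["m"])
            else:
                entry = (label, entry["pi"], True)
        entry = tuple(entry)
        label = str(entry[0])
        if len(entry) == 2 or (len(entry) == 3 and entry[2] is True):
            pi = float(entry[1])
            if not 0 < pi < 1:
                raise ValueError(
                    f"group {label!r}: fixed prevalence must be in (0, 1)"
                )
            labels.append(label)
            k_.append(np.nan)
            m_.append(np.nan)
            pi_.append(pi)
            var_.append(0.0)
            fix_.append(True)
        elif len(entry) == 3:
            k, m = int(entry[1]), int(entry[2])
            if m < 1:
                raise ValueError(f"group {label!r}: m must be >= 1")
            if k <= 0 or k >= m:
                raise ValueError(
                    f"group {label!r}: k={k} of m={m} gives a boundary "
                    "prevalence; the asymptotic theory requires the prevalence "
                    "strictly inside (0, 1)"
                )
            pi = k / m
            labels.append(label)
            k_.append(float(k))
            m_.append(float(m))
            pi_.append(pi)
            var_.append(pi * (1 - pi) / m)
            fix_.append(False)
        else:
            raise ValueError(f"cannot parse prevalence entry {entry!r}")
    return PrevalenceSpec(
        group_labels=labels,
        k=np.array(k_),
        m=np.array(m_),
        pi_hat=np.array(pi_),
        var_pi=np.array(var_),
        fixed=np.array(fix_),
    )


def load_prevalence_config(path) -> PrevalenceSpec:
    """Load prevalence groups from a YAML or JSON file.

    The file holds a list of group mappings, e.g.::

        - {label: nonanginal, k: 146, m: 913}
        - {label: screening, pi: 0.16, fixed: true}
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        entries = json.loads(text)
    else:
        entries = yaml.safe_load(text)
    if isinstance(entries, dict) and "groups" in entries:
        entries = entries["groups"]
    return read_prevalence(entries)
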