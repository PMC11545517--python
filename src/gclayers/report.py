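"""Report assembly: percentage arithmetic, deterministic JSON, schema.

The pipeline report is a plain dict validated against a minimal shipped
schema and serialized deterministically (sorted keys, floats rounded to
9 significant digits) so identical configs and seeds produce
byte-identical files.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "format_percent",
    "exclusion_accounting",
    "group_size_report",
    "jsonify",
    "dump_report",
    "validate_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

#: required top-level report keys and their types
REPORT_SCHEMA: dict[str, type] = {
    "schema_version": int,
    "seed": int,
    "config": dict,
    "stages": dict,
}


def format_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of ``count`` out of ``total``, rounded half-up.

    format_percent(77, 142) == 54.2; format_percent(45, 142, 2) == 31.69;
    format_percent(79, 142, 0) == 56.0.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) / Decimal(total) * 100
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def exclusion_accounting(n_selected: int, n_excluded: int) -> int:
    """Analyzed cohort size after exclusions (e.g. samples lacking
    expression data)."""
    if n_excluded < 0 or n_excluded > n_selected:
        raise ValueError("invalid exclusion count")
    return n_selected - n_excluded


def group_size_report(labels, decimals: int = 1) -> dict:
    """Counts and percentages per group label."""
    import pandas as pd

    labels = pd.Series(labels)
    total = len(labels)
    out = {}
    for g, c in labels.value_counts().sort_index().items():
        out[str(g)] = {"n": int(c), "pct": format_percent(int(c), total, decimals)}
    return out


def _round_sig(x: float, sig: int = 9) -> float:
    if x == 0 or not isinstance(x, float):
        return x
    from math import floor, isfinite, log10

    if not isfinite(x):
        return x
    return round(x, sig - 1 - floor(log10(abs(x))))


def jsonify(obj):
    """Recursively convert to JSON-safe types with deterministic float
    formatting (9 significant digits)."""
    import numpy as np
    import pandas as pd

    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [jsonify(v) for v in (sorted(obj) if isinstance(obj, set) else obj)]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, np.ndarray):
        return [jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {str(k): jsonify(v) for k, v in obj.to_dict(orient="index").items()}
    return obj


def dump_report(report: dict, path) -> None:
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(jsonify(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


def validate_report(report: dict) -> None:
    """Check the report against the shipped minimal schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise TypeError(f"report[{key!r}] must be {typ.__name__}")
    if report["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"report schema version {report['schema_version']} != {SCHEMA_VERSION}"
        )
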