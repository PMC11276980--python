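"""Statistical screen and report assembly.

The robust outlier screen is the Iglewicz-Hoaglin modified z-score:
``M_i = 0.6745 * (x_i - median(x)) / MAD(x)``, two-tailed at |M| > 3.5.
Group comparison delegates to standard routines (Kolmogorov-Smirnov
normality check, unpaired two-sample t test) and reports mean +/- SEM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .core import ValidationError

MODIFIED_Z_CONSTANT = 0.6745


@dataclass
class OutlierScreen:
    values: np.ndarray
    modified_z: np.ndarray
    flags: np.ndarray
    threshold: float


def iglewicz_hoaglin(values, threshold: float = 3.5) -> OutlierScreen:
    """Two-tailed robust screen for multiple outliers via modified z-scores.

    Raises on degenerate spread (MAD = 0) rather than silently falling
    back to another scale estimate.  The screen is single-pass; the
    documented usage after removing a flagged point is to recompute.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValidationError("degenerate spread (MAD = 0)")
    m = MODIFIED_Z_CONSTANT * (x - med) / mad
    return OutlierScreen(
        values=x, modified_z=m, flags=np.abs(m) > threshold, threshold=threshold
    )


def compare_groups(a, b) -> dict:
    """Normality check plus unpaired two-sample t test (equal variances).

    Returns per-group mean +/- SEM, the KS statistic of each group against
    a normal with sample-estimated parameters (a check, not an exact test:
    estimating the parameters makes the nominal KS p-value conservative),
    and the t statistic with its two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")

    def _summary(x: np.ndarray) -> dict:
        ks = sstats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1) or 1.0))
        return {
            "n": int(x.size),
            "mean": float(x.mean()),
            "sem": float(sstats.sem(x)),
            "ks_stat": float(ks.statistic),
            "ks_p": float(ks.pvalue),
        }

    t = sstats.ttest_ind(a, b)
    return {
        "group_a": _summary(a),
        "group_b": _summary(b),
        "t_stat": float(t.statistic),
        "p_value": float(t.pvalue),
    }


def build_report(
    lfp: dict | None = None,
    patch: dict | None = None,
    synaptic: dict | None = None,
    ground_truth: dict | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble a single structured report from per-module results.

    Sections are included only when provided; provenance (config, seed,
    package version) is embedded.  Deterministic for identical inputs.
    """
    from . import __version__

    if lfp is None and patch is None and synaptic is None:
        raise ValidationError("at least one analysis result is required")
    report: dict = {"provenance": {"package_version": __version__}}
    if config is not None:
        report["provenance"]["config"] = config
    if seed is not None:
        report["provenance"]["seed"] = seed
    for key, section in (("lfp", lfp), ("patch", patch), ("synaptic", synaptic),
                         ("ground_truth", ground_truth)):
        if section is not None:
            report[key] = section
    # guarantee the report is JSON-serializable and thus byte-reproducible
    return json.loads(json.dumps(report, default=_jsonify, sort_keys=True))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON-serializable: {type(obj)}")
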