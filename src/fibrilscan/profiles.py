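"""Normalized per-residue stability profiles and hotspot statistics.

Raw mean ΔREU values are min–max normalized to a 0–100 scale per
structure; residues above 40 are *hotspots* (energetically important to
fibril stability), residues below 10 are *neutral*.  Excluded positions
(glycines) stay NA and are skipped — not propagated — by the 5-residue
window smoother, keeping motif-level maps contiguous.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

TOP_THRESHOLD = 40.0
BOTTOM_THRESHOLD = 10.0
EXACT_ENUMERATION_LIMIT = 2_000_000


@dataclass
class ResidueProfile:
    """Per-residue stability profile keyed by author residue number."""

    structure_id: str
    values: dict[int, float | None]  # normalized, None = excluded (NA)
    raw_mean: dict[int, float | None] = field(default_factory=dict)
    window: dict[int, float | None] | None = None

    def non_na(self) -> dict[int, float]:
        return {k: v for k, v in self.values.items() if v is not None}

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.values)
        return pd.DataFrame({
            "residue": keys,
            "raw_mean": [self.raw_mean.get(k) for k in keys],
            "normalized": [self.values[k] for k in keys],
            "windowed": [self.window.get(k) if self.window else None
                         for k in keys],
        })


def normalize_profile(raw, structure_id: str = "") -> ResidueProfile:
    """Min–max normalize mean ΔREU values to [0, 100] per structure.

    NA (None/NaN) entries are preserved.  A degenerate profile (all equal)
    maps to all zeros.  Fewer than two numeric residues is an error.
    """
    clean: dict[int, float | None] = {}
    for k, v in raw.items():
        if v is None or (isinstance(v, float) and np.isnan(v)):
            clean[int(k)] = None
        else:
            clean[int(k)] = float(v)
    vals = [v for v in clean.values() if v is not None]
    if not vals:
        raise ValueError("profile has no numeric residues")
    if len(vals) < 2:
        raise ValueError("profile needs at least 2 numeric residues")
    lo, hi = min(vals), max(vals)
    norm: dict[int, float | None] = {}
    for k, v in clean.items():
        if v is None:
            norm[k] = None
        elif hi == lo:
            norm[k] = 0.0
        else:
            # ratio first, then scale: keeps the endpoints exactly 0/100
            norm[k] = min(100.0, max(0.0, 100.0 * ((v - lo) / (hi - lo))))
    return ResidueProfile(structure_id=structure_id, values=norm,
                          raw_mean=clean)


def window_average(values, w: int = 5) -> dict[int, float | None]:
    """Centred mean over a ``w``-residue window (``w`` odd).

    Windows are truncated at the termini; NA residues are skipped and the
    divisor is the count actually used.  A residue that is itself NA stays
    NA.  Accepts a ResidueProfile or a residue→value mapping.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("window size must be an odd integer >= 1")
    mapping = values.values if isinstance(values, ResidueProfile) else values
    keys = sorted(mapping)
    half = w // 2
    out: dict[int, float | None] = {}
    for i, k in enumerate(keys):
        if mapping[k] is None:
            out[k] = None
            continue
        lo, hi = max(0, i - half), min(len(keys), i + half + 1)
        vals = [mapping[keys[j]] for j in range(lo, hi)
                if mapping[keys[j]] is not None]
        out[k] = float(np.mean(vals))
    return out


def identify_hotspots(profile, top_threshold: float = TOP_THRESHOLD,
                      bottom_threshold: float = BOTTOM_THRESHOLD) -> dict:
    """Partition residues into hotspot (>top) and neutral (<bottom) sets."""
    mapping = profile.values if isinstance(profile, ResidueProfile) else profile
    top = {k for k, v in mapping.items() if v is not None and v > top_threshold}
    bottom = {k for k, v in mapping.items()
              if v is not None and v < bottom_threshold}
    return {"top": top, "bottom": bottom}


# ---------------------------------------------------------------------------
# hydropathy
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def kyte_doolittle_scale() -> dict[str, float]:
    path = resources.files("fibrilscan") / "data" / "kyte_doolittle.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["aa"], df["value"].astype(float)))


@dataclass
class HydropathyTrack:
    sequence: str
    per_residue: list[float]
    window: int
    windowed: list[float]


def hydropathy_profile(sequence: str, w: int = 5) -> HydropathyTrack:
    """Kyte–Doolittle hydropathy with a centred window average."""
    scale = kyte_doolittle_scale()
    seq = sequence.upper()
    bad = sorted(set(seq) - set(scale))
    if bad:
        raise ValueError(f"unknown residue letters: {bad}")
    per = [scale[a] for a in seq]
    win = window_average({i: v for i, v in enumerate(per)}, w)
    return HydropathyTrack(sequence=seq, per_residue=per, window=w,
                           windowed=[win[i] for i in range(len(per))])


# ---------------------------------------------------------------------------
# hotspot-group statistic
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal-approx"


def mann_whitney_exact(group_a, group_b) -> GroupTestResult:
    """Two-tailed Mann–Whitney U test (U reported for the first group).

    Exact by full enumeration of label assignments when there are no ties
    and C(n1+n2, n1) ≤ 2·10⁶; otherwise midranks with the tie-corrected
    normal approximation.  The method field records which path was used.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    from math import comb
    feasible = comb(len(a) + len(b), len(a)) <= EXACT_ENUMERATION_LIMIT
    if not has_ties and feasible:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        method = "normal-approx"
    return GroupTestResult(u_statistic=float(res.statistic),
                           p_two_sided=float(min(res.pvalue, 1.0)),
                           n1=len(a), n2=len(b), method=method)
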