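"""MNase nucleosome-scanning protection profiles from qPCR Ct tables.

Chromatin is digested with micrococcal nuclease (MNase); nucleosome-bound
DNA survives while linker and free DNA are degraded.  Tiled qPCR amplicons
across a region then report local protection: assuming amplification
efficiency 2, the surviving template fraction for an amplicon is
``2**(Ct_undigested - Ct_digested)``, expressed here as percent protection.
Coordinates are 1-based inclusive, numbered from the gene's 5' end; BED
export converts to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Amplicon",
    "ProtectionProfile",
    "CENSORED_CT",
    "percent_protection",
    "protection_profile",
    "design_tiling",
    "compare_profiles",
    "amplicons_to_bed",
]

#: qPCR cycle number at or beyond which a reaction is treated as
#: "no amplification" (censored).
CENSORED_CT = 40.0

#: Protection above this raises a data-quality warning (noise can push
#: values past 100%, but far past it suggests a pipetting or mapping error).
PROTECTION_WARN_PCT = 120.0


@dataclass(frozen=True)
class Amplicon:
    """A qPCR amplicon interval, 1-based inclusive from the gene's 5' end."""

    id: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"amplicon {self.id}: end must exceed start")
        if self.start < 1:
            raise ValueError(f"amplicon {self.id}: coordinates are 1-based")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ProtectionProfile:
    """Per-amplicon percent protection, mean ± sd over qPCR replicates.

    ``data`` columns: amplicon, midpoint, mean_protection, sd_protection,
    n_replicates, censored.  ``normalized`` marks profiles rescaled so the
    maximal amplicon reads 100%.
    """

    data: pd.DataFrame
    condition_label: str = ""
    normalized: bool = False

    def max_normalized(self) -> "ProtectionProfile":
        """Rescale so the most protected amplicon reads 100%."""
        top = float(self.data["mean_protection"].max())
        if top <= 0:
            raise ValueError("cannot normalise an all-zero profile")
        out = self.data.copy()
        out["mean_protection"] = out["mean_protection"] * 100.0 / top
        out["sd_protection"] = out["sd_protection"] * 100.0 / top
        return ProtectionProfile(out, self.condition_label, normalized=True)


def percent_protection(ct_undigested: float, ct_digested: float) -> float:
    """Percent of template protected from MNase digestion.

    ``100 * 2**(Ct_undig - Ct_dig)``: protection depends only on the cycle
    difference, not the template amount.  A censored digested Ct (>=
    :data:`CENSORED_CT` or non-finite) means the template fell below
    detection; 0.0 is returned and the caller should carry the flag.
    """
    if not np.isfinite(ct_undigested) or ct_undigested <= 0:
        raise ValueError(f"undigested Ct must be finite and positive, got {ct_undigested}")
    if not np.isfinite(ct_digested) or ct_digested >= CENSORED_CT:
        return 0.0
    if ct_digested <= 0:
        raise ValueError(f"digested Ct must be positive, got {ct_digested}")
    value = 100.0 * 2.0 ** (ct_undigested - ct_digested)
    if value > PROTECTION_WARN_PCT:
        warnings.warn(
            f"protection {value:.1f}% exceeds {PROTECTION_WARN_PCT:.0f}%; "
            "check replicate pairing and efficiencies"
        )
    return value


def protection_profile(
    ct_table: pd.DataFrame,
    amplicons: Sequence[Amplicon],
    condition_label: str = "",
) -> ProtectionProfile:
    """Build a per-amplicon protection profile from a Ct table.

    ``ct_table`` needs columns ``amplicon``, ``digestion`` (values
    ``digested`` / ``undigested``), ``replicate`` and ``ct``.  Protection is
    computed per replicate from its digested/undigested Ct pair, then
    averaged; amplicons are positioned at their midpoints.  Unknown amplicon
    ids are an error; a missing replicate pair degrades to a warning.
    """
    known = {a.id: a for a in amplicons}
    unknown = set(ct_table["amplicon"]) - set(known)
    if unknown:
        raise ValueError(f"Ct table references unknown amplicons: {sorted(unknown)}")

    rows = []
    for amp_id, group in ct_table.groupby("amplicon", sort=False):
        amp = known[amp_id]
        values, censored = [], 0
        for _, rep in group.groupby("replicate"):
            dig = rep.loc[rep["digestion"] == "digested", "ct"]
            undig = rep.loc[rep["digestion"] == "undigested", "ct"]
            if dig.empty or undig.empty:
                warnings.warn(f"amplicon {amp_id}: incomplete replicate pair skipped")
                continue
            p = percent_protection(float(undig.iloc[0]), float(dig.iloc[0]))
            if p == 0.0:
                censored += 1
            values.append(p)
        if not values:
            warnings.warn(f"amplicon {amp_id}: no usable replicates")
            continue
        arr = np.asarray(values)
        rows.append(
            {
                "amplicon": amp_id,
                "midpoint": amp.midpoint,
                "mean_protection": float(arr.mean()),
                "sd_protection": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "n_replicates": int(arr.size),
                "censored": int(censored),
            }
        )
    data = pd.DataFrame(rows).sort_values("midpoint", ignore_index=True)
    return ProtectionProfile(data=data, condition_label=condition_label)


def design_tiling(
    region_length: int,
    amplicon_size: int = 100,
    size_tol: int = 8,
    overlap: int = 30,
    overlap_tol: int = 10,
    prefix: str = "amp",
) -> list[Amplicon]:
    """Tile a region with overlapping amplicons.

    Amplicons of ``amplicon_size ± size_tol`` bp overlap by
    ``overlap ± overlap_tol`` bp, stepping ``amplicon_size - overlap`` from
    bp 1.  If more than ``size_tol`` bp at the 3' end would stay uncovered,
    a terminal amplicon anchored at the region end is appended (it may
    overlap its neighbour by more than the tolerance).
    """
    if overlap + overlap_tol >= amplicon_size - size_tol:
        raise ValueError("infeasible tolerances: overlap could reach amplicon size")
    if region_length < amplicon_size:
        raise ValueError(
            f"region ({region_length} bp) shorter than amplicon ({amplicon_size} bp)"
        )
    step = amplicon_size - overlap
    starts = list(range(1, region_length - amplicon_size + 2, step))
    amps = [
        Amplicon(id=f"{prefix}{i + 1:02d}", start=s, end=s + amplicon_size - 1)
        for i, s in enumerate(starts)
    ]
    uncovered = region_length - amps[-1].end
    if uncovered > size_tol:
        amps.append(
            Amplicon(
                id=f"{prefix}{len(amps) + 1:02d}",
                start=region_length - amplicon_size + 1,
                end=region_length,
            )
        )
    return amps


def compare_profiles(
    a: ProtectionProfile, b: ProtectionProfile, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-amplicon protection differences (a − b) with Welch tests.

    Returns a table with the difference, its confidence interval and
    p-value per amplicon, plus summary attributes ``trend_mean`` (mean
    signed difference across amplicons — captures an overall sensitivity
    shift even when no single amplicon reaches significance) and
    ``trend_p`` (one-sample t-test of the per-amplicon differences).
    """
    if list(a.data["amplicon"]) != list(b.data["amplicon"]):
        raise ValueError("profiles cover different amplicon sets")
    if a.normalized != b.normalized:
        raise ValueError("cannot compare a raw profile with a max-normalised one")

    rows = []
    for (_, ra), (_, rb) in zip(a.data.iterrows(), b.data.iterrows()):
        diff = ra["mean_protection"] - rb["mean_protection"]
        na, nb = int(ra["n_replicates"]), int(rb["n_replicates"])
        if na > 1 and nb > 1 and (ra["sd_protection"] > 0 or rb["sd_protection"] > 0):
            t, p = stats.ttest_ind_from_stats(
                ra["mean_protection"], ra["sd_protection"], na,
                rb["mean_protection"], rb["sd_protection"], nb,
                equal_var=False,
            )
            se = np.sqrt(ra["sd_protection"] ** 2 / na + rb["sd_protection"] ** 2 / nb)
            # Welch–Satterthwaite dof
            num = se**4
            den = (ra["sd_protection"] ** 2 / na) ** 2 / (na - 1) + (
                rb["sd_protection"] ** 2 / nb
            ) ** 2 / (nb - 1)
            dof = num / den if den > 0 else na + nb - 2
            half = stats.t.ppf(1 - alpha / 2, dof) * se
        else:
            t, p, half = float("nan"), (1.0 if diff == 0 else float("nan")), 0.0
        rows.append(
            {
                "amplicon": ra["amplicon"],
                "midpoint": ra["midpoint"],
                "difference": float(diff),
                "ci_low": float(diff - half),
                "ci_high": float(diff + half),
                "t": float(t),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    diffs = out["difference"].to_numpy()
    out.attrs["trend_mean"] = float(diffs.mean())
    if diffs.size > 1 and diffs.std(ddof=1) > 0:
        _, trend_p = stats.ttest_1samp(diffs, 0.0)
        out.attrs["trend_p"] = float(trend_p)
    else:
        out.attrs["trend_p"] = float("nan")
    return out


def amplicons_to_bed(amplicons: Sequence[Amplicon], chrom: str = "region") -> pd.DataFrame:
    """Amplicon intervals as a 0-based half-open BED table."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [a.start - 1 for a in amplicons],
            "end": [a.end for a in amplicons],
            "name": [a.id for a in amplicons],
        }
    )
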