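"""Synthetic-data generators with known ground truth for every assay.

Each generator emulates the statistical structure of one measurement type
and is deterministic given its (mandatory) seed:

* force–extension series drawn from the Marko–Siggia worm-like chain with
  homoscedastic Gaussian extension noise (bead-tracking error dominates);
* chloroquine-gel topoisomer lanes: band intensities Gaussian in ΔLk
  (Boltzmann distribution of linking number), rendered as a densitometry
  trace of Gaussian band shapes over a smooth background, with the more
  positive (more relaxed) topoisomers at larger migration;
* MNase-scanning qPCR Ct tables implied by a positional nucleosome
  occupancy map and a digestion completeness;
* dual-luciferase tables with a known fold enhancement and lognormal
  replicate scatter.

Composed with the matching estimator, every noiseless generator returns
its truth parameter — the round trips that anchor the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .compensate import LuciferaseSample
from .nucscan import Amplicon, CENSORED_CT
from .topo import LaneProfile
from .wlc import ForceExtensionRecord, ROOM_TEMPERATURE_K, wlc_extension

__all__ = [
    "ForceExtensionTruth",
    "LadderTruth",
    "OccupancyTruth",
    "ReporterTruth",
    "gen_force_extension",
    "gen_topo_lane",
    "gen_ct_table",
    "gen_luciferase",
    "UNFOLDING_TENSION_PN",
]

#: Above this tension nucleosomal fibers unfold; generated points beyond it
#: are emitted but the record is flagged.
UNFOLDING_TENSION_PN = 10.0


def _default_tension_grid() -> tuple:
    """30 log-spaced tensions from 50 fN to 10 pN, the tweezer working range."""
    return tuple(np.geomspace(0.05, 10.0, 30))


@dataclass(frozen=True)
class ForceExtensionTruth:
    """Ground truth for one simulated tether.

    Defaults mirror a bare-DNA tether: persistence length 34 nm and the
    B-form contour of a 5049-bp template (1716.7 nm).
    """

    seed: int
    persistence_length: float = 34.0
    contour_length: float = 5049 * 0.34
    temperature: float = ROOM_TEMPERATURE_K
    tension_grid: tuple = field(default_factory=_default_tension_grid)
    extension_noise_sd: float = 10.0
    condition_label: str = "DNA"

    def __post_init__(self):
        if self.persistence_length <= 0 or self.contour_length <= 0:
            raise ValueError("persistence and contour lengths must be positive")
        grid = np.asarray(self.tension_grid, dtype=float)
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("tension grid must be strictly positive and increasing")
        if self.extension_noise_sd < 0:
            raise ValueError("extension noise sd must be nonnegative")
        object.__setattr__(self, "tension_grid", tuple(grid))


def gen_force_extension(truth: ForceExtensionTruth) -> ForceExtensionRecord:
    """Simulate one tether's tension–extension series.

    The noiseless extension at each grid tension is the worm-like-chain
    inverse (always below the contour length); Gaussian noise of the stated
    sd is then added.  Tensions beyond the unfolding regime are kept but
    flagged.
    """
    rng = np.random.default_rng(truth.seed)
    f = np.asarray(truth.tension_grid)
    x = wlc_extension(f, truth.persistence_length, truth.contour_length, truth.temperature)
    if truth.extension_noise_sd > 0:
        x = x + rng.normal(0.0, truth.extension_noise_sd, size=x.shape)
    flags = ()
    if np.any(f > UNFOLDING_TENSION_PN):
        flags = (f"tension>{UNFOLDING_TENSION_PN:g}pN",)
    return ForceExtensionRecord(
        tether_id=f"sim-fe-{truth.seed}",
        tensions_pn=f,
        extensions_nm=x,
        temperature_k=truth.temperature,
        condition_label=truth.condition_label,
        flags=flags,
    )


@dataclass(frozen=True)
class LadderTruth:
    """Ground truth for one topoisomer lane.

    Band intensities follow ``ln I_k = -a (k - center)^2`` over integer
    linking numbers ``k`` within ``n_bands_each_side`` of the center —
    log-concave in ΔLk, as a Boltzmann linking-number distribution demands.
    ``concentration_param`` is the curvature ``a``.
    """

    seed: int
    center: float = 0.0
    concentration_param: float = 0.3
    n_bands_each_side: int = 3
    band_spacing: float = 50.0
    band_sigma: float = 8.0
    background_level: float = 20.0
    noise_sd: float = 5.0
    peak_intensity: float = 1000.0
    samples_per_spacing: int = 20
    lane_label: str = ""

    def __post_init__(self):
        if self.concentration_param <= 0:
            raise ValueError("concentration_param must be positive")
        if not self.band_sigma < self.band_spacing / 2:
            raise ValueError("bands must be resolvable: band_sigma < band_spacing/2")
        if self.n_bands_each_side < 2:
            raise ValueError("need at least 2 bands on each side of the center")
        if round(self.center) - self.n_bands_each_side <= 1 - self.ORIGIN_SPACINGS:
            raise ValueError("ladder extends past the trace origin; raise ORIGIN_SPACINGS")

    def band_delta_lks(self) -> np.ndarray:
        """Absolute integer linking numbers of the rendered bands."""
        mid = int(round(self.center))
        n = self.n_bands_each_side
        return np.arange(mid - n, mid + n + 1)

    def band_intensities(self) -> np.ndarray:
        """Peak-height intensities of each band (Gaussian in ΔLk)."""
        k = self.band_delta_lks()
        return self.peak_intensity * np.exp(
            -self.concentration_param * (k - self.center) ** 2
        )

    #: Migration coordinate of the absolute ΔLk = 0 topoisomer, in units of
    #: band spacings.  Fixed so that a given topoisomer always runs to the
    #: same place: migration reflects topology, not the distribution, and
    #: lanes from the same gel share this origin.
    ORIGIN_SPACINGS = 10.0

    def band_positions(self) -> np.ndarray:
        """Migration coordinate of each band; +ΔLk migrates further."""
        k = self.band_delta_lks()
        return self.band_spacing * (k + self.ORIGIN_SPACINGS)

    def exact_ladder(self):
        """The truth's band ladder as an indexed :class:`~chromotopo.topo.TopoisomerLadder`.

        Bypasses trace rendering and detection: band intensities are the
        exact Gaussian values, so Morse estimation on this ladder is exact
        up to floating point.  Indices are relative to the brightest band.
        """
        from .topo import Band, TopoisomerLadder, assign_linking_indices

        bands = tuple(
            Band(position=float(p), intensity=float(i))
            for p, i in zip(self.band_positions(), self.band_intensities())
        )
        return assign_linking_indices(
            TopoisomerLadder(bands=bands, lane_label=self.lane_label or f"truth-{self.seed}")
        )

    def absolute_center(self, fit_center_signed: float) -> float:
        """Re-anchor a brightest-band-relative center to absolute ΔLk units."""
        k = self.band_delta_lks()
        brightest = int(k[np.argmax(self.band_intensities())])
        return brightest + fit_center_signed


def gen_topo_lane(truth: LadderTruth) -> LaneProfile:
    """Render a topoisomer ladder as a 1-D densitometry trace.

    The trace is a sum of Gaussian band shapes (height ``I_k``, width
    ``band_sigma``) over a flat background, plus Gaussian read noise.  At
    high chloroquine the more relaxed, more positive-ΔLk topoisomers
    migrate further, so they sit at larger trace coordinates.
    """
    rng = np.random.default_rng(truth.seed)
    centers = truth.band_positions()
    heights = truth.band_intensities()
    step = truth.band_spacing / truth.samples_per_spacing
    positions = np.arange(0.0, centers[-1] + 2.0 * truth.band_spacing, step)
    trace = np.full_like(positions, float(truth.background_level))
    for c, h in zip(centers, heights):
        trace += h * np.exp(-0.5 * ((positions - c) / truth.band_sigma) ** 2)
    if truth.noise_sd > 0:
        trace += rng.normal(0.0, truth.noise_sd, size=trace.shape)
    return LaneProfile(
        positions=positions,
        intensities=np.clip(trace, 0.0, None),
        lane_label=truth.lane_label or f"sim-lane-{truth.seed}",
    )


@dataclass(frozen=True)
class OccupancyTruth:
    """Ground-truth nucleosome occupancy for a scanned region.

    ``nucleosome_intervals`` are 1-based inclusive bp intervals protected
    from MNase; uncovered bases survive digestion with probability
    ``1 - digestion_completeness``.
    """

    seed: int
    region_length: int = 633
    nucleosome_intervals: tuple = ((101, 247), (301, 447), (501, 633))
    digestion_completeness: float = 0.95
    base_ct: float = 20.0
    ct_noise_sd: float = 0.3

    def __post_init__(self):
        ivs = tuple(tuple(iv) for iv in self.nucleosome_intervals)
        last_end = 0
        for s, e in ivs:
            if not (1 <= s <= e <= self.region_length):
                raise ValueError(f"interval ({s},{e}) outside [1,{self.region_length}]")
            if s <= last_end:
                raise ValueError("nucleosome intervals must be non-overlapping and sorted")
            last_end = e
        if not 0.0 <= self.digestion_completeness <= 1.0:
            raise ValueError("digestion_completeness must be in [0,1]")
        object.__setattr__(self, "nucleosome_intervals", ivs)

    def covered_fraction(self, amplicon: Amplicon) -> float:
        """Fraction of the amplicon's bases under a nucleosome."""
        covered = 0
        for s, e in self.nucleosome_intervals:
            covered += max(0, min(e, amplicon.end) - max(s, amplicon.start) + 1)
        return covered / amplicon.length

    def surviving_fraction(self, amplicon: Amplicon) -> float:
        """Template fraction expected to survive digestion for an amplicon."""
        cov = self.covered_fraction(amplicon)
        return cov + (1.0 - cov) * (1.0 - self.digestion_completeness)


def gen_ct_table(
    truth: OccupancyTruth,
    amplicons: Sequence[Amplicon],
    n_replicates: int = 3,
    condition: str = "sim",
) -> pd.DataFrame:
    """Simulate a triplicate MNase-scanning qPCR Ct table.

    Undigested reactions report the input amount (``base_ct``); digested
    reactions shift by ``-log2`` of the surviving template fraction, plus
    Gaussian cycle noise.  An amplicon with no surviving template is
    censored at 40 cycles and flagged ``no amplification``.
    """
    for a in amplicons:
        if a.end > truth.region_length:
            raise ValueError(f"amplicon {a.id} extends beyond the region")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for a in amplicons:
        f = truth.surviving_fraction(a)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "amplicon": a.id,
                    "condition": condition,
                    "digestion": "undigested",
                    "replicate": rep,
                    "ct": truth.base_ct,
                    "flag": "",
                }
            )
            if f <= 0.0:
                ct_dig, flag = CENSORED_CT, "no amplification"
            else:
                noise = rng.normal(0.0, truth.ct_noise_sd) if truth.ct_noise_sd > 0 else 0.0
                ct_dig = truth.base_ct - np.log2(f) + noise
                flag = ""
                if ct_dig >= CENSORED_CT:
                    ct_dig, flag = CENSORED_CT, "no amplification"
            rows.append(
                {
                    "amplicon": a.id,
                    "condition": condition,
                    "digestion": "digested",
                    "replicate": rep,
                    "ct": float(ct_dig),
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReporterTruth:
    """Ground truth for a dual-luciferase experiment series.

    The per-replicate compensation ratio has median ``fold_enhancement``
    and coefficient of variation ``cv`` (lognormal scatter split evenly
    between the two arms).
    """

    seed: int
    fold_enhancement: float = 2.0
    n_replicates: int = 3
    cv: float = 0.15
    renilla_scale: float = 1000.0
    treatment_label: str = "mock"

    def __post_init__(self):
        if self.fold_enhancement <= 0:
            raise ValueError("fold_enhancement must be positive")
        if self.n_replicates < 3:
            raise ValueError("at least three independent experiments are required")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")


def gen_luciferase(truth: ReporterTruth) -> tuple[list[LuciferaseSample], list[LuciferaseSample]]:
    """Simulate paired roX / no-roX dual-luciferase samples.

    Returns ``(rox_samples, no_rox_samples)`` of equal length.  Each arm's
    relative activity carries lognormal scatter with half the stated ratio
    variance, so the per-replicate ratio roX/no-roX has median equal to the
    fold enhancement and coefficient of variation ``cv``.  Renilla readings
    get independent (ratio-irrelevant) scale scatter.
    """
    rng = np.random.default_rng(truth.seed)
    sigma_ratio = np.sqrt(np.log1p(truth.cv**2))
    sigma_arm = sigma_ratio / np.sqrt(2.0)
    rox, no_rox = [], []
    for i in range(1, truth.n_replicates + 1):
        rel_no = 1.0 * np.exp(rng.normal(0.0, sigma_arm)) if truth.cv > 0 else 1.0
        rel_ro = truth.fold_enhancement * (
            np.exp(rng.normal(0.0, sigma_arm)) if truth.cv > 0 else 1.0
        )
        ren_no = truth.renilla_scale * np.exp(rng.normal(0.0, 0.2))
        ren_ro = truth.renilla_scale * np.exp(rng.normal(0.0, 0.2))
        no_rox.append(
            LuciferaseSample(
                sample_id=f"noROX-{i}", plasmid="no_roX",
                firefly=ren_no * rel_no, renilla=ren_no,
                treatment_label=truth.treatment_label,
            )
        )
        rox.append(
            LuciferaseSample(
                sample_id=f"roX-{i}", plasmid="roX",
                firefly=ren_ro * rel_ro, renilla=ren_ro,
                treatment_label=truth.treatment_label,
            )
        )
    return rox, no_rox


def truth_to_dict(truth) -> dict:
    """JSON-ready ground-truth sidecar for any generator truth record."""
    d = asdict(truth)
    d["truth_type"] = type(truth).__name__
    return d
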