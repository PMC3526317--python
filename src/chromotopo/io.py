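"""Plain-text readers and writers for the pipeline's table formats.

Formats (all headered, tab- or comma-separated):

* force–extension TSV: ``tension_pN``, ``extension_nm``
* lane-trace TSV: ``position``, ``intensity``
* Ct CSV: ``amplicon``, ``condition``, ``digestion``, ``replicate``, ``ct``
  (optional ``flag``)
* luciferase CSV: ``sample``, ``plasmid``, ``treatment``, ``firefly``,
  ``renilla``
* amplicon maps as TSV (``id``, ``start``, ``end``; 1-based inclusive) or
  BED (0-based half-open)

Every writer can drop a ``.truth.json`` sidecar next to a simulated file so
downstream checks can recover the generating parameters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .compensate import LuciferaseSample
from .nucscan import Amplicon
from .topo import LaneProfile
from .wlc import ForceExtensionRecord, ROOM_TEMPERATURE_K

__all__ = [
    "write_force_extension",
    "read_force_extension",
    "write_lane",
    "read_lane",
    "write_ct_table",
    "read_ct_table",
    "write_luciferase",
    "read_luciferase",
    "read_amplicons",
    "write_truth_sidecar",
]


def write_truth_sidecar(truth_dict: dict, data_path: str | Path) -> Path:
    """Write a ground-truth JSON sidecar next to a generated data file."""
    path = Path(str(data_path) + ".truth.json")
    path.write_text(json.dumps(truth_dict, indent=2, default=float) + "\n")
    return path


def write_force_extension(record: ForceExtensionRecord, path: str | Path) -> None:
    pd.DataFrame(
        {"tension_pN": record.tensions_pn, "extension_nm": record.extensions_nm}
    ).to_csv(path, sep="\t", index=False)


def read_force_extension(
    path: str | Path,
    tether_id: str | None = None,
    condition_label: str = "",
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> ForceExtensionRecord:
    df = pd.read_csv(path, sep="\t")
    return ForceExtensionRecord(
        tether_id=tether_id or Path(path).stem,
        tensions_pn=df["tension_pN"].to_numpy(),
        extensions_nm=df["extension_nm"].to_numpy(),
        temperature_k=temperature_k,
        condition_label=condition_label,
    )


def write_lane(profile: LaneProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"position": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, sep="\t", index=False)


def read_lane(path: str | Path, lane_label: str | None = None) -> LaneProfile:
    df = pd.read_csv(path, sep="\t")
    return LaneProfile(
        positions=df["position"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        lane_label=lane_label or Path(path).stem,
    )


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"amplicon", "digestion", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_luciferase(samples: Sequence[LuciferaseSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [s.sample_id for s in samples],
            "plasmid": [s.plasmid for s in samples],
            "treatment": [s.treatment_label for s in samples],
            "firefly": [s.firefly for s in samples],
            "renilla": [s.renilla for s in samples],
        }
    ).to_csv(path, index=False)


def read_luciferase(path: str | Path) -> list[LuciferaseSample]:
    df = pd.read_csv(path)
    return [
        LuciferaseSample(
            sample_id=str(r["sample"]),
            plasmid=str(r["plasmid"]),
            firefly=float(r["firefly"]),
            renilla=float(r["renilla"]),
            treatment_label=str(r.get("treatment", "")),
        )
        for _, r in df.iterrows()
    ]


def read_amplicons(path: str | Path) -> list[Amplicon]:
    """Read an amplicon map from TSV (1-based) or BED (0-based half-open)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
        )
        return [
            Amplicon(id=str(r["name"]), start=int(r["start"]) + 1, end=int(r["end"]))
            for _, r in df.iterrows()
        ]
    df = pd.read_csv(path, sep="\t")
    return [
        Amplicon(id=str(r["id"]), start=int(r["start"]), end=int(r["end"]))
        for _, r in df.iterrows()
    ]
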