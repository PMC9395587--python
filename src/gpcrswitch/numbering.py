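"""Ballesteros–Weinstein generic numbering from a helix-anchor annotation.

Labels have the form ``h.nn`` where ``h`` is the transmembrane helix (1–7)
and ``nn = 50 + (residue_id - x50_resid)`` relative to the helix's most
conserved residue (assigned 50). Residues between helices get loop tags:
extracellular loops follow TM2→TM3 (ECL1), TM4→TM5 (ECL2) and TM6→TM7
(ECL3); intracellular loops follow TM1→TM2 (ICL1), TM3→TM4 (ICL2) and
TM5→TM6 (ICL3). Before TM1 is "N-term", after TM7 "C-term".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "HelixAnnotation",
    "BWMap",
    "build_bw_map",
    "resolve",
    "read_annotation",
    "write_annotation",
    "write_bw_map",
]

_LOOP_AFTER = {1: "ICL1", 2: "ECL1", 3: "ICL2", 4: "ECL2", 5: "ICL3", 6: "ECL3"}


@dataclass(frozen=True)
class HelixAnnotation:
    """One helix range with its x50 anchor residue."""

    helix: int
    first_resid: int
    last_resid: int
    x50_resid: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 7:
            raise ValueError(f"helix must be 1–7, got {self.helix}")
        if not self.first_resid <= self.x50_resid <= self.last_resid:
            raise ValueError(
                f"helix {self.helix}: x50 residue {self.x50_resid} outside "
                f"range [{self.first_resid}, {self.last_resid}]"
            )


@dataclass
class BWMap:
    """residue_id → generic label, with the inverse lookup cached."""

    labels: dict[int, str]
    anchors: dict[int, int] = field(default_factory=dict)  # helix → x50 resid

    def label(self, residue_id: int) -> str:
        try:
            return self.labels[residue_id]
        except KeyError:
            raise KeyError(f"residue {residue_id} is not annotated") from None

    def items(self):
        return self.labels.items()


def build_bw_map(
    annotation: list[HelixAnnotation],
    sequence_range: tuple[int, int],
) -> BWMap:
    """Build a total BW map over ``sequence_range`` (inclusive residue ids)."""
    helices = sorted(annotation, key=lambda h: h.helix)
    if len({h.helix for h in helices}) != len(helices):
        raise ValueError("duplicate helix numbers in annotation")
    if len(helices) < 7:
        warnings.warn(
            f"annotation covers only {len(helices)} of 7 helices; "
            "loop tags for missing helices are undefined"
        )
    ordered = sorted(helices, key=lambda h: h.first_resid)
    if [h.helix for h in ordered] != [h.helix for h in helices]:
        raise ValueError("helix ranges must be ascending in helix order")
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.first_resid <= prev.last_resid:
            raise ValueError(
                f"helix ranges overlap: TM{prev.helix} [{prev.first_resid},"
                f"{prev.last_resid}] and TM{cur.helix} [{cur.first_resid},"
                f"{cur.last_resid}]"
            )

    lo, hi = sequence_range
    labels: dict[int, str] = {}
    for resid in range(lo, hi + 1):
        labels[resid] = _label_for(resid, ordered)
    return BWMap(labels=labels, anchors={h.helix: h.x50_resid for h in helices})


def _label_for(resid: int, ordered: list[HelixAnnotation]) -> str:
    for h in ordered:
        if h.first_resid <= resid <= h.last_resid:
            return f"{h.helix}.{50 + (resid - h.x50_resid)}"
    if resid < ordered[0].first_resid:
        return "N-term"
    if resid > ordered[-1].last_resid:
        return "C-term"
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.last_resid < resid < cur.first_resid:
            return _LOOP_AFTER.get(prev.helix, f"loop{prev.helix}{cur.helix}")
    raise AssertionError("unreachable")  # pragma: no cover


def resolve(bw_map: BWMap, label: str) -> int:
    """Residue id bearing ``label``.

    Only helix labels ("h.nn") are uniquely invertible; a loop tag covers
    many residues and raises if requested.
    """
    if not ("." in label and label.split(".")[0].isdigit()):
        raise KeyError(f"label {label!r} is not an invertible helix label")
    for resid, lab in bw_map.labels.items():
        if lab == label:
            return resid
    raise KeyError(f"label {label!r} is absent from the map")


# ---- annotation / map TSV --------------------------------------------------


def read_annotation(path: str | Path) -> list[HelixAnnotation]:
    """Read a helix annotation TSV with columns helix, first, last, x50."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0].lower() in {"helix", "tm"}:
            continue
        helix, first, last, x50 = (int(p) for p in parts[:4])
        out.append(HelixAnnotation(helix, first, last, x50))
    if not out:
        raise ValueError(f"no helix rows in {path}")
    return out


def write_annotation(annotation: list[HelixAnnotation], path: str | Path) -> None:
    lines = ["helix\tfirst\tlast\tx50"]
    for h in sorted(annotation, key=lambda h: h.helix):
        lines.append(f"{h.helix}\t{h.first_resid}\t{h.last_resid}\t{h.x50_resid}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bw_map(bw_map: BWMap, path: str | Path) -> None:
    lines = ["residue_id\tlabel"]
    for resid in sorted(bw_map.labels):
        lines.append(f"{resid}\t{bw_map.labels[resid]}")
    Path(path).write_text("\n".join(lines) + "\n")
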