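"""Shipped annotation fixtures and external-accession management.

The package ships helix-anchor annotation tables for the rat CB1, rat
GPR55 and human CB1 receptors (anchors fixed by the generic labels the
source structures use). Crystal structures and UniProt sequences are not
redistributed; :func:`fetch_accessions` downloads them into the package's
``data/accessions`` cache (or any directory), and :func:`accession_path`
locates a previously fetched copy.
"""

from __future__ import annotations

import urllib.request
from importlib import resources
from pathlib import Path

from .numbering import HelixAnnotation, read_annotation

__all__ = [
    "annotation",
    "accession_path",
    "fetch_accessions",
    "PDB_ACCESSIONS",
    "UNIPROT_ACCESSIONS",
]

ANNOTATIONS = ("cb1_rat", "cb1_human", "gpr55_rat")
PDB_ACCESSIONS = ("5TGZ", "5XRA")
UNIPROT_ACCESSIONS = ("P21554", "P20272", "F1MAK4", "Q08BG4", "Q9Y2T6")

_PDB_URL = "https://files.rcsb.org/download/{}.pdb"
_UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{}.fasta"


def _data_dir() -> Path:
    return Path(resources.files("gpcrswitch") / "data")


def annotation(name: str) -> list[HelixAnnotation]:
    """Load a shipped helix-anchor annotation ("cb1_rat", "cb1_human",
    "gpr55_rat")."""
    if name not in ANNOTATIONS:
        raise ValueError(f"unknown annotation {name!r}; choose from {ANNOTATIONS}")
    return read_annotation(_data_dir() / f"{name}_bw.tsv")


def annotation_path(name: str) -> Path:
    if name not in ANNOTATIONS:
        raise ValueError(f"unknown annotation {name!r}")
    return _data_dir() / f"{name}_bw.tsv"


def accession_path(accession: str, search_dirs: list[Path] | None = None) -> Path | None:
    """Path of a fetched accession file, or None if absent.

    PDB ids map to ``<ID>.pdb``, UniProt ids to ``<ACC>.fasta``.
    """
    fname = (
        f"{accession}.pdb" if accession in PDB_ACCESSIONS else f"{accession}.fasta"
    )
    dirs = list(search_dirs or []) + [_data_dir() / "accessions"]
    for d in dirs:
        p = Path(d) / fname
        if p.is_file():
            return p
    return None


def fetch_accessions(
    dest: str | Path | None = None, timeout: float = 30.0
) -> dict[str, Path]:
    """Download all required crystal structures and sequences.

    Requires network access to files.rcsb.org and rest.uniprot.org; raises
    ``OSError`` when unreachable. Returns accession → file path.
    """
    dest = Path(dest) if dest is not None else _data_dir() / "accessions"
    dest.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    jobs = [(a, _PDB_URL.format(a), f"{a}.pdb") for a in PDB_ACCESSIONS] + [
        (a, _UNIPROT_URL.format(a), f"{a}.fasta") for a in UNIPROT_ACCESSIONS
    ]
    for acc, url, fname in jobs:
        target = dest / fname
        if not target.is_file():
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                target.write_bytes(resp.read())
        out[acc] = target
    return out
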