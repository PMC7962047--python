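"""Reading and writing the pipeline's on-disk formats.

FASTQ records follow the simulator's dialect: the description field carries
``np=<int> rq=<float>`` for the consensus pass count and mean read accuracy.
Tables are tab-separated; pipeline outputs start with a ``#`` header line
naming the producing version and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .simulate import ReadRecord

_NP_RE = re.compile(r"np=(\d+)")
_RQ_RE = re.compile(r"rq=([0-9.eE+-]+)")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load consensus reads, parsing np=/rq= metadata from the description."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        m_np = _NP_RE.search(rec.description)
        m_rq = _RQ_RE.search(rec.description)
        records.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                pass_count=int(m_np.group(1)) if m_np else None,
                read_quality=float(m_rq.group(1)) if m_rq else None,
            )
        )
    return records


def write_tract_fastq(path: str | Path, tracts: Iterable[tuple[str, str]]) -> None:
    """Write extracted repeat tracts as plain FASTQ (constant quality)."""
    with open(Path(path), "w") as fh:
        for read_id, tract in tracts:
            fh.write(f"@{read_id}\n{tract}\n+\n{'I' * len(tract)}\n")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: str | Path, cfg_hash: str = "") -> None:
    """Write a TSV with a provenance header line."""
    with open(Path(path), "w") as fh:
        fh.write(f"# repeatlens {__version__} config={cfg_hash or 'n/a'}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Genotype TSV with columns sample, marker, allele1, allele2."""
    frame = read_table(path)
    required = {"sample", "marker", "allele1", "allele2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"genotype table lacks columns: {sorted(missing)}")
    return frame
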