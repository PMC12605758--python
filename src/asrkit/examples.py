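"""Packaged example data."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def toy_gene_gff3_path() -> Path:
    """Path to the packaged toy gene: 33 bp, three isoforms (16, 9, 19 bp)
    over a 25-bp coding footprint, hence ASR = 44/25 = 1.76."""
    return Path(resources.files("asrkit").joinpath("data/toy_gene.gff3"))
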