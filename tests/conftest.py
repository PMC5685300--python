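from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make pileup_oracle importable

from fetalfrac.panel import HomozygousPanel, PanelEntry, SnpLocus

SAM_HEADER = (
    "@HD\tVN:1.6\tSO:coordinate\n"
    "@SQ\tSN:chr1\tLN:100000\n"
    "@SQ\tSN:chr2\tLN:100000\n"
)


def sam_line(
    qname: str,
    chrom: str = "chr1",
    pos: int = 9990,
    seq: str = "A" * 20,
    flag: int = 0,
    mapq: int = 60,
    cigar: str | None = None,
    qual: str | None = None,
) -> str:
    cigar = cigar or f"{len(seq)}M"
    qual = qual or "I" * len(seq)  # Q40
    return f"{qname}\t{flag}\t{chrom}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"


@pytest.fixture
def write_sam(tmp_path):
    """Write SAM text (header prepended) to a temp file, return path + text."""

    def _write(*read_lines: str, header: str = SAM_HEADER):
        text = header + "".join(read_lines)
        path = tmp_path / "reads.sam"
        path.write_text(text)
        return path, text

    return _write


@pytest.fixture
def toy_panel() -> HomozygousPanel:
    """Three autosomal loci with maternal alleles A, C, G."""
    return HomozygousPanel(
        [
            PanelEntry(SnpLocus("1", 10000, "A", "G"), "A"),
            PanelEntry(SnpLocus("1", 10050, "C", "T"), "C"),
            PanelEntry(SnpLocus("2", 500, "G", "A"), "G"),
        ]
    )
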