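"""Brute-force per-base pileup oracle, independent of the pysam-based path.

Parses SAM text directly and walks CIGAR strings one base at a time; used to
cross-check allele counting on small fixtures.
"""

from __future__ import annotations

import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPP = 0x800


def _norm(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def naive_pileup(sam_text: str, min_bq: int = 20, min_mq: int = 20,
                 exclude_dup: bool = True) -> dict:
    """Per-site observations: (chrom, pos1) -> {qname: (base|None, qual)}.

    Mate overlaps are collapsed keeping the higher-quality base; deletions and
    reference skips over a site record base None.
    """
    obs: dict[tuple, dict[str, tuple]] = {}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        qname, flag, chrom, pos, mapq, cigar, seq, qual = (
            f[0], int(f[1]), _norm(f[2]), int(f[3]), int(f[4]), f[5], f[9], f[10]
        )
        if flag & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPP):
            continue
        if exclude_dup and flag & FLAG_DUP:
            continue
        if mapq < min_mq:
            continue
        rpos = pos  # 1-based reference cursor
        qpos = 0  # 0-based query cursor
        for n, op in _CIGAR_RE.findall(cigar):
            n = int(n)
            if op in "M=X":
                for i in range(n):
                    _record(obs, chrom, rpos + i, qname, seq[qpos + i],
                            ord(qual[qpos + i]) - 33)
                rpos += n
                qpos += n
            elif op in "DN":
                for i in range(n):
                    _record(obs, chrom, rpos + i, qname, None, -1)
                rpos += n
            elif op in "IS":
                qpos += n
            # H, P consume neither
    return obs


def _record(obs, chrom, rpos, qname, base, qual):
    site = obs.setdefault((chrom, rpos), {})
    prev = site.get(qname)
    if prev is None or qual > prev[1]:
        site[qname] = (base, qual)


def oracle_counts(sam_text: str, panel_sites: dict, min_bq: int = 20,
                  min_mq: int = 20, exclude_dup: bool = True) -> dict:
    """Counts per panel site: (chrom, pos) -> (n_maternal, n_nonmaternal, n_discarded).

    ``panel_sites`` maps (chrom, pos1) -> maternal_allele.
    """
    obs = naive_pileup(sam_text, min_bq, min_mq, exclude_dup)
    out = {}
    for key, maternal in panel_sites.items():
        key = (_norm(key[0]), key[1])
        site = obs.get(key)
        if not site:
            continue
        n_mat = n_non = n_disc = 0
        for base, qual in site.values():
            if base is None or base not in "ACGT" or qual < min_bq:
                n_disc += 1
            elif base == maternal:
                n_mat += 1
            else:
                n_non += 1
        out[key] = (n_mat, n_non, n_disc)
    return out
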