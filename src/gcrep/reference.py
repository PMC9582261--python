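"""Germline reference handling for IGH heavy-chain analysis.

The reference is the coordinate authority for everything downstream: V genes
are stored in the IMGT-gapped dialect (gap character ``.``) and FR/CDR
boundaries are derived once, at load time, from IMGT unique numbering
(codons FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104).  All
coordinates handed to other modules are 0-based half-open intervals on the
ungapped sequence.

The packaged mini-reference (6 V, 3 J, 7 CH1 segments) is a *synthetic*
stand-in generated with a fixed seed; it follows the real IMGT layout but
its sequences are not biological genes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Human IGHC locus order used throughout (IgD/IgE omitted; never analysed).
ISOTYPES = ("M", "G3", "G1", "A1", "G2", "G4", "A2")

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")
#: IMGT unique numbering: region boundaries in codons (half-open, 0-based).
_IMGT_CODON_BOUNDS = {
    "FR1": (0, 26),
    "CDR1": (26, 38),
    "FR2": (38, 55),
    "CDR2": (55, 65),
    "FR3": (65, 104),
}
#: Gapped V length implied by IMGT numbering through the end of FR3.
IMGT_GAPPED_LENGTH = 104 * 3

_ALPHABET = set("ACGTN")
_R, _Y, _W = set("AG"), set("CT"), set("AT")


class ReferenceError(ValueError):
    """A reference sequence violates the germline contract."""


class ParseError(ValueError):
    """A reference file is not valid FASTA."""


def motif_positions(seq: str) -> tuple[frozenset[int], frozenset[int]]:
    """Positions covered by AID hotspot motifs on the given strand.

    RGYW (R=A/G, Y=C/T, W=A/T) and its reverse-complement WRCY are scanned
    separately; every position of a motif occurrence counts as inside that
    motif. A position may belong to both sets.
    """
    rgyw, wrcy = set(), set()
    for i in range(len(seq) - 3):
        a, b, c, d = seq[i : i + 4]
        if a in _R and b == "G" and c in _Y and d in _W:
            rgyw.update(range(i, i + 4))
        if a in _W and b in _R and c == "C" and d in _Y:
            wrcy.update(range(i, i + 4))
    return frozenset(rgyw), frozenset(wrcy)


@dataclass(frozen=True)
class VGene:
    name: str
    gapped: str
    seq: str = field(init=False, default="")
    regions: dict = field(init=False, default_factory=dict)

    def __post_init__(self):
        if len(self.gapped) != IMGT_GAPPED_LENGTH:
            raise ReferenceError(
                f"V gene {self.name}: gapped length {len(self.gapped)} does not "
                f"match IMGT numbering ({IMGT_GAPPED_LENGTH} nt through FR3)"
            )
        ungapped = self.gapped.replace(".", "")
        if not set(ungapped) <= _ALPHABET:
            raise ReferenceError(f"V gene {self.name}: invalid characters")
        object.__setattr__(self, "seq", ungapped)
        # Map each IMGT codon boundary onto the ungapped coordinate by
        # counting non-gap characters before it.
        regions = {}
        for region, (c0, c1) in _IMGT_CODON_BOUNDS.items():
            start = sum(1 for ch in self.gapped[: c0 * 3] if ch != ".")
            end = sum(1 for ch in self.gapped[: c1 * 3] if ch != ".")
            if end <= start:
                raise ReferenceError(f"V gene {self.name}: empty region {region}")
            regions[region] = (start, end)
        object.__setattr__(self, "regions", regions)

    @property
    def region_map(self) -> np.ndarray:
        """Per-position region label over the ungapped sequence."""
        labels = np.empty(len(self.seq), dtype=object)
        for region, (s, e) in self.regions.items():
            labels[s:e] = region
        return labels

    def region_of(self, pos: int) -> str:
        for region, (s, e) in self.regions.items():
            if s <= pos < e:
                return region
        raise IndexError(f"position {pos} outside V gene {self.name}")

    @property
    def hotspot_sets(self) -> tuple[frozenset[int], frozenset[int]]:
        return motif_positions(self.seq)


@dataclass(frozen=True)
class JGene:
    name: str
    seq: str
    fr4_start: int

    def __post_init__(self):
        if not set(self.seq) <= _ALPHABET:
            raise ReferenceError(f"J gene {self.name}: invalid characters")
        if not 0 <= self.fr4_start < len(self.seq):
            raise ReferenceError(f"J gene {self.name}: fr4_start out of range")


@dataclass(frozen=True)
class CSegment:
    subclass: str  # one of ISOTYPES
    seq: str

    @property
    def isotype(self) -> str:
        """Class-level isotype letter (M, G or A)."""
        return self.subclass[0]


@dataclass(frozen=True)
class GermlineReference:
    v_genes: dict[str, VGene]
    j_genes: dict[str, JGene]
    c_segments: dict[str, CSegment]

    def __post_init__(self):
        if not self.v_genes:
            raise ReferenceError("empty germline reference: no V genes")
        if not self.j_genes:
            raise ReferenceError("empty germline reference: no J genes")
        subs = sorted(self.c_segments)
        for i, a in enumerate(subs):
            for b in subs[i + 1 :]:
                sa, sb = self.c_segments[a].seq, self.c_segments[b].seq
                n = min(len(sa), len(sb))
                diff = sum(x != y for x, y in zip(sa[:n], sb[:n]))
                if diff < 3:
                    raise ReferenceError(
                        f"CH1 segments {a} and {b} differ at only {diff} positions "
                        "(need >=3 for subclass assignment)"
                    )


def _check_fasta(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}: line {lineno}: expected FASTA header")
                return
    raise ParseError(f"{path}: line 1: empty file")


def load_germline(v_fasta_path, j_fasta_path, c_fasta_path) -> GermlineReference:
    """Load an IMGT-gapped V FASTA, a J FASTA and a CH1 FASTA.

    J headers carry ``fr4_start=<int>``; C headers are named ``IGH<subclass>``
    (IGHM, IGHG1, ..., IGHA2).
    """
    for p in (v_fasta_path, j_fasta_path, c_fasta_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
        _check_fasta(p)
    v_genes = {}
    for rec in SeqIO.parse(str(v_fasta_path), "fasta"):
        v_genes[rec.id] = VGene(name=rec.id, gapped=str(rec.seq).upper())
    j_genes = {}
    for rec in SeqIO.parse(str(j_fasta_path), "fasta"):
        fr4 = None
        for tok in rec.description.split():
            if tok.startswith("fr4_start="):
                fr4 = int(tok.split("=", 1)[1])
        if fr4 is None:
            raise ReferenceError(f"J gene {rec.id}: missing fr4_start annotation")
        j_genes[rec.id] = JGene(name=rec.id, seq=str(rec.seq).upper(), fr4_start=fr4)
    c_segments = {}
    for rec in SeqIO.parse(str(c_fasta_path), "fasta"):
        if not rec.id.startswith("IGH"):
            raise ReferenceError(f"C segment {rec.id}: name must be IGH<subclass>")
        subclass = rec.id[3:]
        if subclass not in ISOTYPES:
            raise ReferenceError(f"C segment {rec.id}: unknown subclass {subclass!r}")
        c_segments[subclass] = CSegment(subclass=subclass, seq=str(rec.seq).upper())
    return GermlineReference(v_genes=v_genes, j_genes=j_genes, c_segments=c_segments)


@lru_cache(maxsize=1)
def builtin_reference() -> GermlineReference:
    """The packaged synthetic mini-reference (6 V, 3 J, 7 CH1)."""
    data = resources.files("gcrep") / "data"
    return load_germline(
        data / "synthetic_ighv.fasta",
        data / "synthetic_ighj.fasta",
        data / "synthetic_ighc_ch1.fasta",
    )


def gene_of(call: str) -> str:
    """Gene-level name of an allele call (``IGHV1-1*01`` -> ``IGHV1-1``)."""
    return call.split("*", 1)[0]
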