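"""Generate the synthetic pre-numbered numbering templates shipped as
package data.  The sequences are germline-like, canonical-length VH/VL
domains authored for this package (synthetic; not copied from any
database record); labels are constructed so that the shipped boundary
tables extract the intended canonical CDRs under each scheme.
"""
import json
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "src" / "abrkit" / "data" / "templates.json"


def seq_concat(parts):
    return "".join(parts)


# ----- heavy template (116 aa) -----
H_FR1 = "EVQLLESGGGLVQPGGSLRLSCAASGFTFS"   # Kabat 1-30
H_H1 = "SYAMS"                            # Kabat 31-35
H_FR2 = "WVRQAPGKGLEWVS"                  # Kabat 36-49
H_H2 = "AISGSGGSTYYADSVK"                 # Kabat 50-65
H_FR3 = "RFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK"  # Kabat 66-94 incl. 82A/B/C
H_H3 = "DRGYSSWY"                         # Kabat 95-102
H_FR4 = "WGQGTLVTVSS"                     # Kabat 103-113
heavy_seq = seq_concat([H_FR1, H_H1, H_FR2, H_H2, H_FR3, H_H3, H_FR4])
assert len(heavy_seq) == 116, len(heavy_seq)

kabat_h = [str(i) for i in range(1, 83)] + ["82A", "82B", "82C"] + \
    [str(i) for i in range(83, 114)]
assert len(kabat_h) == 116

# ----- light (kappa) template (107 aa) -----
L_FR1 = "DIQMTQSPSSLSASVGDRVTITC"  # 1-23
L_L1 = "RASQSISSYLN"               # 24-34
L_FR2 = "WYQQKPGKAPKLLIY"          # 35-49
L_L2 = "AASSLQS"                   # 50-56
L_FR3 = "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC"  # 57-88
L_L3 = "QQSYSTPPT"                 # 89-97
L_FR4 = "FGQGTKVEIK"               # 98-107
light_seq = seq_concat([L_FR1, L_L1, L_FR2, L_L2, L_FR3, L_L3, L_FR4])
assert len(light_seq) == 107, len(light_seq)

kabat_l = [str(i) for i in range(1, 108)]


def imgt_block(n, lo, hi, anchor="both"):
    """IMGT labels for a block of n residues over slots lo..hi.

    CDR blocks fill from both ends toward the middle (IMGT gap rule);
    framework blocks anchor on the CDR-facing edges.
    """
    slots = [str(i) for i in range(lo, hi + 1)]
    if n > len(slots):
        raise ValueError("block longer than slot range")
    if anchor == "left":
        return slots[:n]
    if anchor == "right":
        return slots[-n:]
    k = (n + 1) // 2
    return slots[:k] + slots[len(slots) - (n - k):]


# IMGT heavy: CDR1 = GFTFSSYA (seq idx 25-32), CDR2 = ISGSGGST (idx 50-57),
# CDR3 = AK+H3 (idx 95-104)
imgt_h = (
    imgt_block(25, 1, 26, "right")      # FR1: idx 0-24
    + imgt_block(8, 27, 38)             # CDR1: idx 25-32
    + imgt_block(17, 39, 55, "right")   # FR2: idx 33-49
    + imgt_block(8, 56, 65)             # CDR2: idx 50-57
    + imgt_block(37, 66, 104)           # FR3: idx 58-94
    + imgt_block(10, 105, 117)          # CDR3: idx 95-104
    + imgt_block(11, 118, 128, "left")  # FR4: idx 105-115
)
assert len(imgt_h) == 116

# IMGT light: CDR1 = QSISSY (idx 26-31), CDR2 = AAS (idx 49-51),
# CDR3 = QQSYSTPPT (idx 88-96)
imgt_l = (
    imgt_block(26, 1, 26, "right")      # FR1: idx 0-25
    + imgt_block(6, 27, 38)             # CDR1
    + imgt_block(17, 39, 55, "right")   # FR2: idx 32-48
    + imgt_block(3, 56, 65)             # CDR2
    + imgt_block(36, 66, 104)           # FR3: idx 52-87
    + imgt_block(9, 105, 117)           # CDR3
    + imgt_block(10, 118, 128, "left")  # FR4: idx 97-106
)
assert len(imgt_l) == 107

for labels in (kabat_h, imgt_h, kabat_l, imgt_l):
    assert len(labels) == len(set(labels))

templates = [
    {
        "id": "vh-template-1",
        "chain": "heavy",
        "sequence": heavy_seq,
        "labels": {"kabat": kabat_h, "chothia": kabat_h, "imgt": imgt_h},
    },
    {
        "id": "vl-kappa-template-1",
        "chain": "light",
        "sequence": light_seq,
        "labels": {"kabat": kabat_l, "chothia": kabat_l, "imgt": imgt_l},
    },
]

OUT.write_text(json.dumps(
    {"version": "abrkit-templates-1",
     "comment": "Synthetic pre-numbered canonical-length VH/VL numbering "
                "templates with parallel Kabat/Chothia/IMGT labels.",
     "templates": templates}, indent=1) + "\n")
print("wrote", OUT)
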