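"""Six-region annotations shared by the consensus and CDR machinery.

Antibody variable domains carry three binding loops per chain.  Whatever
the defining convention — structural-consensus ABRs or the Kabat,
Chothia and IMGT CDRs — an annotation is six residue spans, three on the
light chain (L1, L2, L3) and three on the heavy chain (H1, H2, H3),
expressed as inclusive 0-based residue-index ranges in the query chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

LIGHT_REGIONS = ("L1", "L2", "L3")
HEAVY_REGIONS = ("H1", "H2", "H3")
REGION_NAMES = LIGHT_REGIONS + HEAVY_REGIONS

#: chain role of each region
REGION_ROLE = {**{r: "light" for r in LIGHT_REGIONS},
               **{r: "heavy" for r in HEAVY_REGIONS}}

SCHEMES = ("paratome", "kabat", "chothia", "imgt")

Span = tuple[int, int]  # inclusive residue-index range


@dataclass
class RegionAnnotation:
    """Six region spans for one antibody, under one defining scheme.

    ``spans[region]`` is an inclusive ``(start, end)`` pair of residue
    indices in the corresponding chain, or ``None`` for an empty region.
    """

    antibody_id: str
    scheme: str
    spans: dict[str, Span | None]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in REGION_NAMES:
            self.spans.setdefault(name, None)
        for role, names in (("light", LIGHT_REGIONS), ("heavy", HEAVY_REGIONS)):
            prev_end = -1
            for name in names:
                span = self.spans[name]
                if span is None:
                    continue
                s, e = span
                if not (0 <= s <= e):
                    raise ValueError(f"bad span for {name}: {span}")
                if s <= prev_end:
                    raise ValueError(
                        f"{role} spans overlap or are out of order at {name}")
                prev_end = e

    def region_residues(self, region: str) -> set[tuple[str, int]]:
        span = self.spans[region]
        if span is None:
            return set()
        role = REGION_ROLE[region]
        return {(role, i) for i in range(span[0], span[1] + 1)}

    def residues(self) -> set[tuple[str, int]]:
        """All annotated residues as (chain role, residue index) keys."""
        out: set[tuple[str, int]] = set()
        for name in REGION_NAMES:
            out |= self.region_residues(name)
        return out

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "antibody_id": self.antibody_id,
            "scheme": self.scheme,
            "spans": {k: list(v) if v else None for k, v in self.spans.items()},
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionAnnotation":
        spans = {k: tuple(v) if v else None for k, v in d["spans"].items()}
        return cls(d["antibody_id"], d["scheme"], spans, d.get("meta", {}))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RegionAnnotation":
        return cls.from_dict(json.loads(text))
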