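# abrkit

Identification of antibody **antigen-binding regions (ABRs)** from
structural consensus, and quantitative comparison against the classical
CDR definitions (Kabat, Chothia, IMGT).

## The problem

The residues through which an antibody binds its antigen are usually
assumed to lie in the complementarity-determining regions (CDRs), which
each numbering scheme defines as fixed label intervals on the variable
domain.  Real antibody-antigen complexes tell a subtler story: a
substantial fraction of the residues actually touching the antigen fall
*outside* every CDR definition, yet almost all of them fall inside six
regions of structural consensus.  Across a multiple structure alignment
of antibodies bound to their antigens, certain aligned positions contact
the antigen in antibody after antibody; the maximal stretches of columns
in which at least a fraction θ of antibodies (default θ = 0.10,
inclusive) make such contacts form exactly three regions per chain —
the ABRs.  abrkit is for structural immunologists and antibody engineers
who need the *binding* regions, not just the hypervariable ones.

The package implements:

- **structure_io** — PDB parsing of heavy/light/antigen complexes
  (gemmi), residue-residue contacts at an atom-distance cutoff
  (default 6 Å, any atom pair), Kabsch superposition;
- **consensus** — reference-anchored multiple structure alignment,
  per-column contact fractions, derivation and projection of the frozen
  ABR boundaries;
- **schemes** — Kabat/Chothia/IMGT numbering by template transfer,
  CDR extraction from boundary tables, scheme conversion;
- **annotate** — transfer of ABRs to new antibodies from sequence
  (framework-anchored Smith-Waterman to the best reference hit) or
  from structure (framework superposition + nearest-Cα matching);
- **curation** — chain classification, complex screening, sequence
  clustering (identity ≥ 0.97, coverage ≥ 0.95) and contact-fingerprint
  redundancy removal (similarity ≥ 0.77, shorter-list denominator);
- **evaluate** — precision/recall against observed binding residues,
  consensus/Δ method comparison, per-region statistics, method-unique
  binding residues, ΔΔG ternary classification at ±0.25 kcal/mol;
- **fixtures** — synthetic antibody-like complexes and families with
  planted contacts and known ABR spans, so the whole pipeline is
  testable without downloads.

The training/transfer cycle is wrapped in a scikit-learn style
estimator, `AbrConsensus` (`fit` on complexes, `predict` on sequences
or structures).

## Worked example

```python
from abrkit import AbrConsensus, extract_contacts, score_annotation
from abrkit.fixtures import FixtureSpec, generate_family

train = generate_family(FixtureSpec(seed=7), n=20)
model = AbrConsensus(theta=0.10).fit([m.structure for m in train.members])
print(model.definition_.spans)

query = train.members[0].structure
ann = model.predict([(query.heavy.sequence, query.light.sequence)])[0]
ann.antibody_id = query.pdb_id
gold = extract_contacts(query, 6.0).ab_residue_keys()
counts, precision, recall = score_annotation(ann, gold)
print(f"precision {precision:.2f}  recall {recall:.2f}")
```

prints

```
{'L1': (23, 33), 'L2': (45, 55), 'L3': (88, 96), 'H1': (30, 34), 'H2': (49, 62), 'H3': (97, 104)}
precision 0.55  recall 0.94
```

The six spans are inclusive alignment-column ranges of the fitted ABR
definition — here they recover the generator's planted regions exactly.
The precision/recall line scores the sequence-route annotation of one
antibody against its observed 6 Å binding residues: recall is high
because nearly all contacts lie inside the ABRs, precision is moderate
because regions also contain non-binding residues (the usual trade-off
at a permissive contact cutoff).

A thin CLI mirrors the library: `abrkit annotate`, `abrkit fixtures`,
`abrkit contacts` (see `--help`).

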