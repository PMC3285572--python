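# Methods

## Model

An antibody's antigen-binding regions (ABRs) are defined operationally,
not by sequence variability: align many antibody-antigen complexes into
a common column system, mark in each antibody the residues whose atoms
come within a cutoff d of any antigen atom, and take the maximal runs
of columns in which at least a fraction θ of the antibodies make such
contacts.  Empirically these runs form exactly three stretches per
chain; their column ranges, frozen at training time, are the ABR
definition.  New antibodies are annotated by *transfer*: boundaries are
carried over from the best-matching annotated antibody, never re-derived
from a single query's contacts.  A consequence of freezing is that a
query residue can bind antigen yet fall outside its transferred ABR;
this is by design — the definition encodes consensus, not per-complex
truth.

Assumptions: one heavy and one light chain per antibody, a single
protein antigen of at least five residues, conventional two-domain Fv
architecture (no single-domain antibodies), and contacts measured over
all atoms present in the deposited coordinates (crystal structures
rarely include hydrogens; no atom filtering is applied; for alternate
conformations the highest-occupancy altloc is kept, ties resolved by
file order).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| contact cutoff d | 6.0 | Å | any-atom distance defining a residue contact; 4-6 Å all give the same qualitative picture |
| consensus threshold θ | 0.10 | fraction | minimum share of antibodies contacting at a column (inclusive ≥); denominator is *all* antibodies, gapped rows included |
| gap_merge | 2 | columns | sub-threshold gap bridged when merging consensus runs; 0 gives strict maximal runs |
| regions_per_chain | 3 | — | enforced region count; excess runs merge closest-first, a deficit is an error |
| Cα match radius | 4.0 | Å | residue correspondence in structural alignment and transfer |
| identity / coverage | 0.97 / 0.95 | fraction | sequence clustering thresholds (identity over the shorter length; coverage both ways) |
| contact-similarity cutoff | 0.77 | fraction | redundancy within clusters; shared contacts over the shorter list |
| FR floor | 0.4 identity over ≥ 50 aa | — | minimum credible framework alignment for sequence transfer |
| ΔΔG band | ±0.25 | kcal/mol | ternary stabilizing/neutral/destabilizing classification (neutral band closed) |

## Multiple structure alignment

The alignment that the consensus is computed on is a reference-anchored
progressive superposition: the structure with the most resolved Cα
atoms across both antibody chains anchors the column system (ties to
the smallest id); every other antibody is sequence-pre-anchored to the
reference, rigidly fitted by Kabsch on the common Cα pairs, and its
residues are assigned to reference columns by mutual-nearest Cα within
4 Å, kept order-consistent by a longest-increasing-subsequence filter;
unmatched residues open insertion columns.  This replaces a dedicated
multiple-structure aligner: the scientific content being reproduced is
the consensus/boundary logic, which is agnostic to the aligner, and an
externally computed alignment can be injected via
`consensus.aligned_set_from_rows`.

## Annotation transfer

*Sequence route.*  Each chain independently finds its highest-scoring
reference entry by Smith-Waterman (BLOSUM62, gap open 11 / extend 1 —
standard protein-search defaults; highest score stands in for lowest
E-value).  The hit's four framework segments are then locally aligned
to the query in order, each within the suffix after the previous
segment, and each query ABR is the stretch strictly between consecutive
framework matches.  Local alignment trims mismatching framework
termini; because the segment length is known, the trimmed residues are
reclaimed by gap-free edge extension rather than leaking into the ABR.
Aligning segments separately means a poorly matching middle framework
fails loudly instead of silently shifting its neighbours.  When the
best heavy-chain and light-chain hits disagree, each chain keeps its
own hit (logged).

*Structure route.*  The query chain is superposed onto the best hit's
chain on framework Cα pairs; residues match by nearest Cα within 4 Å
and the hit's spans map through the correspondence.  A framework RMSD
above 5 Å aborts the transfer as unreliable.  On mildly diverged
fixtures the two routes assign ≥ 99% of residues identically, which is
what justifies using the sequence route when no structure exists.

## Numbering and CDR baselines

Kabat/Chothia/IMGT numbering is template transfer: the query is
globally aligned to a pre-numbered template of its chain type and
labels are carried across; insertions relative to the template receive
lettered labels at the scheme's anchor position for the enclosing CDR
(the Kabat and Chothia anchors differ in L1/H1, encoded in
`data/scheme_tables.json`).  CDRs are label intervals from the same
versioned table, so alternate boundary revisions can be pinned as data.
The shipped templates (`data/templates.json`, regenerable with
`scripts/build_numbering_templates.py`) are **synthetic**
canonical-length VH/VL sequences authored for this package with
parallel labels under all three schemes.  Their CDR-boundary labels are
exact per the tables; IMGT framework-interior label placement is
approximate (slots anchored at the CDR edges), which cannot affect CDR
extraction but means interior IMGT framework labels should not be
quoted against an external numbering service.  Scheme conversion is the
fixed label-to-label map read off the parallel-numbered templates, with
insertion letters carried through base positions.

## Synthetic data: what it emulates and what it does not

The fixture generator emulates the *statistical* structure of the
training data: families of related antibodies (default: the packaged
templates mutated at 5% per position, optionally with a planted indel
inside one region) whose binding residues concentrate in six planted
spans.  Contacts inside the spans recur independently per member at
density 0.5; contacts outside are *sporadic* — drawn without
replacement from a family-wide pool of outside columns at expected
density 0.02 — because non-recurrence at aligned positions is exactly
the property that separates background contacts from consensus regions.
The default planted spans deviate from the template's Kabat CDRs in the
two places where consensus regions characteristically differ from CDRs
(L2 extended four residues N-terminal; H2 ending two residues short),
so ABR/CDR difference sets are non-trivial by construction.

Geometry is schematic: a zig-zag Cα trace at 5 Å column spacing with
one dummy side-chain atom per residue, antigen atoms placed 5.0 Å from
planted-contact side chains and ≥ 8 Å from everything else.  Passing
tests on fixtures therefore demonstrate the correctness of the contact
logic, alignment bookkeeping, consensus statistics and transfer
algebra — they do **not** demonstrate numbering fidelity on exotic real
antibodies, robustness to low-resolution or incomplete structures, or
the published benchmark figures, all of which require real PDB data
(the tests that need it fetch at run time and fail without network).

## Numerical and design choices

- Threshold semantics are inclusive (a column at exactly θ is in a
  span) and the θ denominator counts all antibodies, not just non-gap
  rows; both are configurable where the convention is genuinely open.
- Tie-breaks are deterministic everywhere: best-hit ties go to higher
  identity then smaller id; co-optimal local alignments prefer longer,
  then earlier in the query; redundancy representatives prefer more
  contacts then smaller id; closest-run merging prefers the leftmost
  pair.  No global random state is used; fixtures derive one stream per
  seed.
- Degenerate inputs: superposition refuses fewer than three points or
  collinear sets; empty contact fingerprints compare as similarity 0
  with a warning; an annotation with an empty prediction reports
  precision as missing (excluded from macro averages) and recall 0.
- Macro averaging (per antibody) is the primary evaluation convention;
  pooled counts are used for the consensus/Δ coverage table.
- Chain classification thresholds are alignment-score-based per class
  rather than E-values, since E-values are search-tool artifacts; the
  veto rule (an antibody call passing any TCR/MHC threshold is
  discarded) reproduces the conservative receptor-exclusion behaviour.

## Acceptance problem sizes

`scripts/acceptance.py` uses 20 training and 20 test complexes per run,
a size at which boundary recovery is exact under the default densities
and the whole run takes seconds; all reported quantities are recomputed
from the seed at run time.

## Known limitations

- No support for single-domain (VHH) antibodies, non-protein antigens,
  multi-antigen complexes, or symmetry-mate reconstruction.
- Numbering covers sequences within template-transfer reach (≥ 50%
  framework identity to a template); heavily engineered or germline-
  distant sequences may be unnumberable.
- The Honegger-Plückthun and enhanced-Chothia schemes are out of scope,
  as are canonical-loop classification and any energy calculation
  (ΔΔG values are classified, never computed).
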