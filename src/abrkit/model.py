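"""Scikit-learn style estimator over the consensus/transfer pipeline.

``AbrConsensus.fit`` consumes a training set of antibody-antigen
complexes, builds the multiple structure alignment, derives the frozen
ABR column boundaries and annotates every training antibody —
producing the annotated reference set.  ``predict`` then annotates new
antibodies: sequence pairs go through framework-anchored local
alignment to the best reference hit, structures through rigid
superposition.  The estimator composes with sklearn pipelines and
``get_params``/``set_params``-based model selection.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .annotate import AnnotatedReferenceSet, ReferenceEntry, \
    infer_abrs_sequence, infer_abrs_structure
from .consensus import align_antibody_set, build_column_profiles, \
    derive_abr_boundaries, map_abrs_to_antibody
from .regions import RegionAnnotation
from .structure_io import ComplexStructure

__all__ = ["AbrConsensus"]


class AbrConsensus(BaseEstimator):
    """Identify antigen-binding regions by structural contact consensus.

    Parameters
    ----------
    theta:
        Consensus threshold — minimum fraction of training antibodies
        contacting the antigen at an aligned column (inclusive).
    gap_merge:
        Maximum number of sub-threshold columns bridged when merging
        adjacent consensus stretches.
    cutoff:
        Atom-atom contact distance cutoff in Angstrom.
    ca_match:
        Maximum Cα-Cα distance for residue correspondence during
        structural alignment and transfer.

    Attributes
    ----------
    aligned_ : AlignedAntibodySet
        The training multiple structure alignment.
    profiles_ : list of ColumnProfile
        Per-column contact fraction and occupancy.
    definition_ : AbrDefinition
        The frozen six-region column boundaries.
    reference_set_ : AnnotatedReferenceSet
        Training antibodies with projected ABR annotations; the search
        target of :meth:`predict`.
    """

    def __init__(self, theta: float = 0.10, gap_merge: int = 2,
                 cutoff: float = 6.0, ca_match: float = 4.0,
                 min_chain_length: int = 60):
        self.theta = theta
        self.gap_merge = gap_merge
        self.cutoff = cutoff
        self.ca_match = ca_match
        self.min_chain_length = min_chain_length

    def fit(self, X: list[ComplexStructure], y=None) -> "AbrConsensus":
        """Derive ABR boundaries from training complexes."""
        aligned = align_antibody_set(
            X, cutoff=self.cutoff, ca_match=self.ca_match,
            min_chain_length=self.min_chain_length)
        profiles = build_column_profiles(aligned)
        defn = derive_abr_boundaries(
            profiles, theta=self.theta, gap_merge=self.gap_merge,
            provenance={"training_ids": list(aligned.ids),
                        "n_columns": dict(aligned.n_columns),
                        "reference_id": aligned.reference_id})
        by_id = {s.pdb_id: s for s in X}
        entries = []
        for ab in aligned.ids:
            rows = {role: aligned.rows[role][ab] for role in ("heavy", "light")}
            ann = map_abrs_to_antibody(defn, rows, ab)
            s = by_id[ab]
            entries.append(ReferenceEntry(ab, s.heavy.sequence,
                                          s.light.sequence, ann, s))
        self.aligned_ = aligned
        self.profiles_ = profiles
        self.definition_ = defn
        self.reference_set_ = AnnotatedReferenceSet(entries)
        return self

    def predict(self, X) -> list[RegionAnnotation]:
        """Annotate queries: ``(heavy, light)`` sequence pairs use the
        sequence route, :class:`ComplexStructure` items the structure
        route."""
        check_is_fitted(self, "reference_set_")
        out = []
        for i, item in enumerate(X):
            if isinstance(item, ComplexStructure):
                out.append(infer_abrs_structure(
                    item, self.reference_set_, ca_match=self.ca_match))
            else:
                heavy, light = item
                out.append(infer_abrs_sequence(
                    heavy, light, self.reference_set_,
                    antibody_id=f"query{i}"))
        return out

    transform = predict
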