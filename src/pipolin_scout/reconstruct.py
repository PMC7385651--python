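"""Pipolin reconstruction from detector hits.

The element's bounds are the att direct repeats; the repeat that
overlaps a tRNA gene lying on the opposite strand is the right end
(attR) by convention, and all atts must head in the same direction
because they are direct repeats.  Those two assumptions suffice to
assign att roles, orient and order pipolin-bearing contigs, and join
them into a single continuous sequence with explicit assembly gaps of
unknown (here: fixed, configurable) length.

Coordinates are 0-based half-open throughout; "canonical orientation"
of a fragment is the orientation in which its atts lie on the '+'
strand (so attR sits at the right with its tRNA on '-').
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .core import FeatureHit, GenomeAssembly, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "AttRepeat",
    "PipolinFragment",
    "ScaffoldedPipolin",
    "AmbiguousAttError",
    "InconsistentStructureError",
    "NoPipolinError",
    "assign_att_roles",
    "collect_pipolin_fragments",
    "orient_and_order",
    "scaffold",
    "classify_structure",
    "reconstruct_pipolin",
]

STRUCTURE_CLASSES = (
    "complete_single_contig",
    "complete_scaffolded",
    "three_att_prophage",
    "unbounded_piPolB_only",
    "inconsistent",
)


class AmbiguousAttError(ValueError):
    """More than one att overlaps a tRNA on the opposite strand."""


class InconsistentStructureError(ValueError):
    """Hits contradict the direct-repeat / attR-rightmost assumptions."""


class NoPipolinError(ValueError):
    """No piPolB hit: the genome carries no pipolin (a signal, not a failure)."""


@dataclass
class AttRepeat:
    hit: FeatureHit
    role: str = "unassigned"  # attL | attR | att_internal | unassigned
    overlaps_trna: bool = False
    fallback_used: bool = False


def _overlaps_opposite_trna(att: FeatureHit, trnas: list[FeatureHit]) -> bool:
    return any(
        att.overlaps(t) and t.strand != att.strand
        for t in trnas
    )


def assign_att_roles(
    atts: list[AttRepeat], trnas: list[FeatureHit]
) -> list[AttRepeat]:
    """Assign attL/attR/att_internal roles.

    The att overlapping a tRNA on the opposite strand is attR; the att
    farthest from it in canonical orientation is attL; any atts between
    them are internal.  Without a tRNA anchor the rightmost att in
    canonical orientation becomes attR and the assignment is flagged
    low-confidence (``fallback_used``).
    """
    if not atts:
        raise ValueError("no att repeats to assign")
    for a in atts:
        a.overlaps_trna = _overlaps_opposite_trna(a.hit, trnas)
    anchored = [a for a in atts if a.overlaps_trna]
    if len(anchored) > 1:
        raise AmbiguousAttError(
            "multiple atts overlap opposite-strand tRNAs: "
            + ", ".join(f"{a.hit.contig_id}:{a.hit.start}-{a.hit.end}" for a in anchored)
        )
    fallback = not anchored
    if anchored:
        att_r = anchored[0]
    else:
        # canonical strand = strand of the best-scoring att; rightmost on
        # that strand (in canonical orientation) plays attR
        best = max(atts, key=lambda a: a.hit.score)
        canon = best.hit.strand
        same = [a for a in atts if a.hit.strand == canon] or atts
        if canon == "+":
            att_r = max(same, key=lambda a: a.hit.end)
        else:
            att_r = min(same, key=lambda a: a.hit.start)
        logger.warning(
            "no tRNA anchor: falling back to rightmost att as attR (low confidence)"
        )
    att_r.role = "attR"
    att_r.fallback_used = fallback

    others = [a for a in atts if a is not att_r]
    if others:
        def distance_key(a: AttRepeat) -> float:
            if a.hit.contig_id != att_r.hit.contig_id:
                return float("inf")
            return abs(a.hit.start - att_r.hit.start)

        att_l = max(others, key=distance_key)
        att_l.role = "attL"
        att_l.fallback_used = fallback
        for a in others:
            if a is not att_l:
                a.role = "att_internal"
                a.fallback_used = fallback
    return atts


@dataclass
class PipolinFragment:
    """One contig's contribution to a pipolin: an interval on the contig,
    an orientation, and the features that fall inside the interval
    (contig coordinates, pre-orientation)."""

    contig_id: str
    start: int
    end: int
    sequence: str
    reverse: bool = False
    features: list[FeatureHit] = field(default_factory=list)
    att_roles: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start

    def oriented_sequence(self) -> str:
        return revcomp(self.sequence) if self.reverse else self.sequence

    def oriented_features(self) -> list[FeatureHit]:
        """Features in the fragment's own (oriented) coordinate system."""
        out = []
        for f in self.features:
            s, e = f.start - self.start, f.end - self.start
            strand = f.strand
            if self.reverse:
                s, e = self.length - e, self.length - s
                strand = "-" if strand == "+" else "+"
            out.append(f.moved(start=s, end=e, strand=strand,
                               contig_id=self.contig_id))
        out.sort(key=lambda f: f.start)
        return out


def collect_pipolin_fragments(
    assembly: GenomeAssembly,
    pipolb_hits: list[FeatureHit],
    atts: list[AttRepeat],
    trnas: list[FeatureHit],
) -> list[PipolinFragment]:
    """One fragment per contig carrying a piPolB or an att hit.

    A bounding att clips the fragment at the element edge it defines
    (in canonical orientation: attL fragment runs from the att to the
    contig end, attR fragment from the contig start to the att, the
    single-contig two-att case from attL to attR); contigs without a
    bounding att contribute whole.
    """
    if not pipolb_hits:
        raise NoPipolinError("no piPolB hit: not a pipolin-positive genome")
    by_contig: dict[str, dict] = {}
    for h in pipolb_hits:
        by_contig.setdefault(h.contig_id, {"pipolb": [], "atts": []})["pipolb"].append(h)
    for a in atts:
        by_contig.setdefault(a.hit.contig_id, {"pipolb": [], "atts": []})["atts"].append(a)

    fragments: list[PipolinFragment] = []
    for cid, group in by_contig.items():
        contig = assembly.contigs[cid]
        L = len(contig)
        catts = sorted(group["atts"], key=lambda a: a.hit.start)
        roles = {a.role for a in catts}
        strands = {a.hit.strand for a in catts}
        if len(strands) > 1:
            anchored = any(a.overlaps_trna for a in catts)
            if not anchored:
                raise InconsistentStructureError(
                    f"atts on opposite strands within contig {cid} with no tRNA anchor"
                )
            raise InconsistentStructureError(
                f"atts on opposite strands within contig {cid}"
            )
        start, end = 0, L
        if "attL" in roles and "attR" in roles:
            start = min(a.hit.start for a in catts if a.role in ("attL", "attR"))
            end = max(a.hit.end for a in catts if a.role in ("attL", "attR"))
        elif "attL" in roles:
            att = next(a for a in catts if a.role == "attL")
            if att.hit.strand == "+":
                start, end = att.hit.start, L
            else:
                start, end = 0, att.hit.end
        elif "attR" in roles:
            att = next(a for a in catts if a.role == "attR")
            if att.hit.strand == "+":
                start, end = 0, att.hit.end
            else:
                start, end = att.hit.start, L
        # extend attR fragments so an overlapping tRNA is fully retained
        contained = []
        for f in group["pipolb"]:
            if start <= f.start and f.end <= end:
                contained.append(f)
        for a in catts:
            if start <= a.hit.start and a.hit.end <= end:
                contained.append(a.hit.moved(query_id=a.role if a.role != "unassigned" else "att"))
        for t in trnas:
            if t.contig_id == cid and t.start < end and start < t.end:
                contained.append(t.moved(start=max(t.start, start), end=min(t.end, end)))
        fragments.append(
            PipolinFragment(
                contig_id=cid,
                start=start,
                end=end,
                sequence=contig[start:end],
                features=sorted(contained, key=lambda f: f.start),
                att_roles=roles - {"unassigned"},
            )
        )
    return fragments


def _pipolb_strand_oriented(frag: PipolinFragment) -> Optional[str]:
    for f in frag.oriented_features():
        if f.feature_type == "piPolB":
            return f.strand
    return None


def orient_and_order(fragments: list[PipolinFragment]) -> list[PipolinFragment]:
    """Orient every fragment into canonical direction (atts on '+') and
    order them attL fragment, middle fragment(s), attR fragment.

    Att-less middle fragments are oriented so their piPolB strand matches
    the majority piPolB strand of the att-anchored fragments (ties: '+')
    and ordered by descending piPolB score.  Contradictory role
    placements raise :class:`InconsistentStructureError`.
    """
    if not fragments:
        raise ValueError("no fragments to orient")
    first = [f for f in fragments if "attL" in f.att_roles]
    last = [f for f in fragments if "attR" in f.att_roles]
    if len(first) > 1 or len(last) > 1:
        raise InconsistentStructureError("multiple fragments claim the same att role")

    # orientation of att-bearing fragments: flip so atts lie on '+'
    for f in fragments:
        att_strands = {ft.strand for ft in f.features if ft.feature_type == "att"}
        if len(att_strands) > 1:
            raise InconsistentStructureError(
                f"mixed att strands within fragment {f.contig_id}"
            )
        if att_strands:
            f.reverse = att_strands == {"-"}

    if first and last and first[0] is last[0] and len(fragments) > 1:
        # a complete element on one contig: stray extra fragments are dropped
        extra = [f for f in fragments if f is not first[0]]
        for f in extra:
            logger.warning("dropping stray fragment %s outside complete element",
                           f.contig_id)
        return [first[0]]

    anchored = [f for f in fragments if f.att_roles]
    middles = [f for f in fragments if not f.att_roles]

    # majority piPolB strand among oriented anchored fragments decides the
    # orientation of att-less middles
    strands = [s for f in anchored if (s := _pipolb_strand_oriented(f))]
    majority = "+"
    if strands and strands.count("-") > strands.count("+"):
        majority = "-"
    for f in middles:
        for feat in f.features:
            if feat.feature_type == "piPolB":
                # current orientation strand vs desired
                cur = _pipolb_strand_oriented(f)
                if cur is not None and cur != majority:
                    f.reverse = not f.reverse
                break

    def mid_key(f: PipolinFragment) -> tuple:
        scores = [ft.score for ft in f.features if ft.feature_type == "piPolB"]
        has_pipolb = bool(scores)
        return (not has_pipolb, -(max(scores) if scores else 0.0), f.contig_id)

    middles.sort(key=mid_key)
    internal_only = [
        f for f in anchored
        if f.att_roles and not (f.att_roles & {"attL", "attR"})
    ]
    tail = [] if (first and last and last[0] is first[0]) else last
    ordered = first + [m for m in middles] + internal_only + tail
    seen = {id(f) for f in ordered}
    leftovers = [f for f in fragments if id(f) not in seen]
    for f in leftovers:
        logger.warning("dropping fragment %s with no role or piPolB", f.contig_id)
    if not ordered:
        raise InconsistentStructureError("no orderable fragments")
    return ordered


@dataclass
class ScaffoldedPipolin:
    """The reconstructed element: ordered oriented fragments joined by
    N-runs, with all features lifted into rendered coordinates."""

    genome_id: str
    fragments: list[PipolinFragment]
    gap_length: int
    sequence: str
    features: list[FeatureHit]
    structure_class: str = "unbounded_piPolB_only"
    low_confidence: bool = False
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = sum(f.length for f in self.fragments)
        expected += self.gap_length * max(0, len(self.fragments) - 1)
        if len(self.sequence) != expected:
            raise ValueError("rendered length != fragments + gaps")

    def features_of(self, ftype: str) -> list[FeatureHit]:
        return [f for f in self.features if f.feature_type == ftype]

    def summary(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "structure_class": self.structure_class,
            "low_confidence": self.low_confidence,
            "length": len(self.sequence),
            "n_fragments": len(self.fragments),
            "fragments": [
                {
                    "contig_id": f.contig_id,
                    "start": f.start,
                    "end": f.end,
                    "reverse_complemented": f.reverse,
                }
                for f in self.fragments
            ],
            "n_att": len(self.features_of("att")),
            "n_piPolB": len(self.features_of("piPolB")),
            "notes": self.notes,
        }


def scaffold(
    ordered_fragments: list[PipolinFragment],
    gap_length: int = 100,
    genome_id: str = "pipolin",
    low_confidence: bool = False,
) -> ScaffoldedPipolin:
    """Concatenate oriented fragments with ``gap_length`` Ns between
    consecutive fragments, recording an assembly_gap feature per junction
    and lifting all fragment features into rendered coordinates."""
    if not ordered_fragments:
        raise ValueError("cannot scaffold an empty fragment list")
    parts: list[str] = []
    features: list[FeatureHit] = []
    offset = 0
    for i, frag in enumerate(ordered_fragments):
        if i > 0:
            features.append(
                FeatureHit(
                    query_id="assembly_gap", contig_id=genome_id,
                    start=offset, end=offset + gap_length, strand="+",
                    feature_type="assembly_gap",
                )
            )
            parts.append("N" * gap_length)
            offset += gap_length
        for f in frag.oriented_features():
            features.append(
                f.moved(start=offset + f.start, end=offset + f.end,
                        contig_id=genome_id)
            )
        parts.append(frag.oriented_sequence())
        offset += frag.length
    features.sort(key=lambda f: f.start)
    pip = ScaffoldedPipolin(
        genome_id=genome_id,
        fragments=ordered_fragments,
        gap_length=gap_length,
        sequence="".join(parts),
        features=features,
        low_confidence=low_confidence,
    )
    pip.structure_class = classify_structure(pip)
    _validate_structure(pip)
    return pip


def _validate_structure(pip: ScaffoldedPipolin) -> None:
    atts = pip.features_of("att")
    roles = {a.query_id for a in atts}
    if {"attL", "attR"} <= roles:
        ordered = sorted(atts, key=lambda a: a.start)
        if ordered[0].query_id != "attL" or ordered[-1].query_id != "attR":
            pip.structure_class = "inconsistent"
            pip.notes.append("att roles out of positional order in rendered space")
            return
        pipolbs = pip.features_of("piPolB")
        if not any(ordered[0].end <= p.start and p.end <= ordered[-1].start
                   for p in pipolbs):
            pip.structure_class = "inconsistent"
            pip.notes.append("no piPolB strictly between attL and attR")
            return
        if len({a.strand for a in atts}) > 1:
            pip.structure_class = "inconsistent"
            pip.notes.append("att strands differ in rendered space")


def classify_structure(pipolin: ScaffoldedPipolin) -> str:
    """complete_single_contig | complete_scaffolded | three_att_prophage |
    unbounded_piPolB_only | inconsistent"""
    if pipolin.structure_class == "inconsistent":
        return "inconsistent"
    n_att = len(pipolin.features_of("att"))
    n_frag = len(pipolin.fragments)
    if n_att >= 3:
        return "three_att_prophage"
    if n_att == 2:
        return "complete_single_contig" if n_frag == 1 else "complete_scaffolded"
    return "unbounded_piPolB_only"


def reconstruct_pipolin(
    assembly: GenomeAssembly,
    pipolb_hits: list[FeatureHit],
    att_hits: list[FeatureHit],
    trna_hits: list[FeatureHit],
    gap_length: int = 100,
) -> Optional[ScaffoldedPipolin]:
    """End-to-end reconstruction: role assignment, fragment collection,
    orientation/ordering, scaffolding, classification.

    Returns None when no piPolB hit exists (not a pipolin-positive
    genome).  Structures whose hits contradict the model are returned
    with ``structure_class='inconsistent'`` rather than raised."""
    if not pipolb_hits:
        return None
    atts = [AttRepeat(hit=h) for h in att_hits]
    low_conf = False
    try:
        if atts:
            assign_att_roles(atts, trna_hits)
            low_conf = any(a.fallback_used for a in atts)
        fragments = collect_pipolin_fragments(assembly, pipolb_hits, atts, trna_hits)
        ordered = orient_and_order(fragments)
        return scaffold(ordered, gap_length=gap_length,
                        genome_id=assembly.genome_id, low_confidence=low_conf)
    except (InconsistentStructureError, AmbiguousAttError) as exc:
        logger.warning("%s: inconsistent structure (%s)", assembly.genome_id, exc)
        # best effort: whole contigs, input orientation, flagged inconsistent
        frags = []
        carrying = {h.contig_id for h in pipolb_hits} | {a.hit.contig_id for a in atts}
        for cid in carrying:
            contig = assembly.contigs[cid]
            feats = [h for h in pipolb_hits if h.contig_id == cid]
            feats += [a.hit for a in atts if a.hit.contig_id == cid]
            feats += [t for t in trna_hits if t.contig_id == cid]
            frags.append(
                PipolinFragment(contig_id=cid, start=0, end=len(contig),
                                sequence=contig,
                                features=sorted(feats, key=lambda f: f.start))
            )
        pip = scaffold(frags, gap_length=gap_length,
                       genome_id=assembly.genome_id, low_confidence=True)
        pip.structure_class = "inconsistent"
        pip.notes.append(str(exc))
        return pip
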