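"""Alignment-column classification and the identical match ratio.

Each column of a translated local alignment is one of: an identical match
(i, same standard residue on both rows), a homologous substitution (h,
distinct residues with positive BLOSUM62 score — the "+" of a search-tool
midline), a non-similar mismatch (m, score <= 0, or any X/stop), or a gap
column (g).  The identical match ratio i/(i+h) over the conserved region
measures substitution flexibility: low values mean the protein tolerates
many conservative replacements.  Gap and mismatch columns never enter the
ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .align import (DEFAULT_SCHEME, GAP, LocalAlignment, ScoringScheme,
                    STANDARD_AA, best_translated_hit)
from .io import RunConfig, SequenceRecord

logger = logging.getLogger("planaflex")


class UndefinedRatioError(ValueError):
    """Raised when an alignment has no identical or homologous columns."""


@dataclass(frozen=True)
class MatchProfile:
    """Column counts of one conserved region."""

    i: int
    h: int
    m: int
    g: int

    def __post_init__(self):
        if min(self.i, self.h, self.m, self.g) < 0:
            raise ValueError("column counts must be non-negative")

    @property
    def n_columns(self) -> int:
        return self.i + self.h + self.m + self.g

    @property
    def region_len_nt(self) -> int:
        """Nucleotide span of the conserved region, gap columns excluded."""
        return 3 * (self.i + self.h + self.m)


def classify_columns(aligned_query: str, aligned_subject: str,
                     scheme: ScoringScheme = DEFAULT_SCHEME) -> MatchProfile:
    """Classify every alignment column into i / h / m / g.

    X and '*' columns are never i nor h: X rows of BLOSUM62 are
    non-positive and stops are not residues, so both fall to m.  A column
    with gaps on both rows is rejected (such columns cannot arise from a
    pairwise alignment).
    """
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned strings must have equal length")
    i = h = m = g = 0
    for a, b in zip(aligned_query, aligned_subject):
        if a == GAP and b == GAP:
            raise ValueError("column with gaps on both rows")
        if a == GAP or b == GAP:
            g += 1
        elif a == b and a in STANDARD_AA:
            i += 1
        elif a in STANDARD_AA and b in STANDARD_AA and scheme.score(a, b) > 0:
            h += 1
        else:
            m += 1
    return MatchProfile(i, h, m, g)


def identical_match_ratio(profile: MatchProfile) -> float:
    """i/(i+h) over the conserved region, in [0, 1]."""
    if profile.i + profile.h == 0:
        raise UndefinedRatioError(
            "ratio undefined: no identical or homologous columns")
    return profile.i / (profile.i + profile.h)


@dataclass
class HomologPair:
    """A query/subject unigene pair with its best alignment and statistic."""

    query_id: str
    subject_id: str
    alignment: LocalAlignment
    profile: MatchProfile
    ratio: float | None
    query_len_nt: int
    passed_filters: bool = True
    fail_reasons: list[str] = field(default_factory=list)


FILTER_ORDER = ("query_length", "evalue", "region_length")


def filter_pairs(pairs: list[HomologPair], config: RunConfig
                 ) -> tuple[list[HomologPair], pd.DataFrame]:
    """Apply the homolog-pair filter cascade and report attrition.

    A pair is retained iff query length >= min_query_len_nt AND E-value
    <= max_evalue_pair AND conserved-region span >= min_region_nt (all
    boundaries inclusive).  The attrition report counts each removed pair
    under the first criterion it fails, in the order length, E-value,
    region; the pair itself records every criterion it fails.
    """
    removed = dict.fromkeys(FILTER_ORDER, 0)
    retained: list[HomologPair] = []
    for pair in pairs:
        reasons = []
        if pair.query_len_nt < config.min_query_len_nt:
            reasons.append("query_length")
        if pair.alignment.evalue is None or pair.alignment.evalue > config.max_evalue_pair:
            reasons.append("evalue")
        if pair.profile.region_len_nt < config.min_region_nt:
            reasons.append("region_length")
        pair.fail_reasons = reasons
        pair.passed_filters = not reasons
        if reasons:
            removed[reasons[0]] += 1
        else:
            retained.append(pair)
    report = pd.DataFrame({
        "criterion": list(FILTER_ORDER),
        "removed": [removed[c] for c in FILTER_ORDER],
    })
    report.loc[len(report)] = ["retained", len(retained)]
    logger.info("filter_pairs: %d in, %d retained (%s)", len(pairs),
                len(retained), removed)
    return retained, report


def build_pairs(query_set: list[SequenceRecord],
                subject_set: list[SequenceRecord],
                scheme: ScoringScheme = DEFAULT_SCHEME,
                config: RunConfig | None = None,
                pairing: dict[str, str] | None = None) -> list[HomologPair]:
    """Best translated hit per query, with profile, ratio and filter flags.

    By default every query is searched against every subject and the best
    subject by raw score wins (ties go to the lexicographically smallest
    subject id).  ``pairing`` restricts each query to one named subject —
    the fast path for simulated panels whose pairing is known.  Pairs whose
    ratio is undefined (no i or h columns) are dropped and logged.
    """
    if not query_set or not subject_set:
        raise ValueError("both sequence sets must be non-empty")
    config = config or RunConfig()
    by_id = {s.id: s for s in subject_set}
    pairs: list[HomologPair] = []
    undefined = 0
    for query in query_set:
        if pairing is not None:
            candidates = [by_id[pairing[query.id]]]
        else:
            candidates = sorted(subject_set, key=lambda s: s.id)
        best = None
        for subject in candidates:
            hit = best_translated_hit(query, subject, scheme)
            if hit is None:
                continue
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        if best is None:
            continue
        prof = classify_columns(best.aligned_query, best.aligned_subject, scheme)
        try:
            ratio = identical_match_ratio(prof)
        except UndefinedRatioError:
            undefined += 1
            logger.info("build_pairs: %s vs %s has undefined ratio, dropped",
                        query.id, best.subject_id)
            continue
        pairs.append(HomologPair(query.id, best.subject_id, best, prof,
                                 ratio, len(query.seq)))
    if undefined:
        logger.info("build_pairs: %d pair(s) dropped with undefined ratio",
                    undefined)
    filter_pairs(pairs, config)
    return pairs


def pairs_to_table(pairs: list[HomologPair]) -> pd.DataFrame:
    """Flatten pairs into the TSV pair-report layout."""
    rows = []
    for p in pairs:
        rows.append({
            "query_id": p.query_id,
            "subject_id": p.subject_id,
            "query_frame": p.alignment.query_frame,
            "subject_frame": p.alignment.subject_frame,
            "score": p.alignment.raw_score,
            "evalue": p.alignment.evalue,
            "i": p.profile.i, "h": p.profile.h,
            "m": p.profile.m, "g": p.profile.g,
            "region_nt": p.profile.region_len_nt,
            "ratio": p.ratio,
            "passed": p.passed_filters,
            "fail_reasons": ";".join(p.fail_reasons),
        })
    return pd.DataFrame(rows)
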