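"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline has a parameter-recovery test built
on these generators, so nothing depends on external sequence databases.
Coding-sequence pairs evolve under a three-way per-codon substitution
spectrum (identical / conservative / radical, judged by BLOSUM62 sign),
with synonymous codons drawn uniformly and optional whole-codon indels.
The generators log every site event, so each expected statistic can be
computed from the log without re-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ScoringScheme, DEFAULT_SCHEME, ALPHABET
from .io import SequenceRecord

# codon tables for the 20 standard residues (standard genetic code)
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_AA_BY_CODON = {}
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _aa = _TABLE[16 * _i + 4 * _j + _k]
            _AA_BY_CODON[_b1 + _b2 + _b3] = _aa
            if _aa != "*":
                _CODONS.setdefault(_aa, []).append(_b1 + _b2 + _b3)


def conservative_partners(scheme: ScoringScheme = DEFAULT_SCHEME) -> dict[str, list[str]]:
    """Residue -> distinct residues with positive substitution score.

    Under BLOSUM62 three residues (C, G, P) have no positive off-diagonal
    partner; they get an empty list here and the generators avoid placing
    them at sites where a conservative substitution may be requested.
    """
    out: dict[str, list[str]] = {}
    for a in ALPHABET[:20]:
        out[a] = [b for b in ALPHABET[:20] if b != a and scheme.score(a, b) > 0]
    return out


def radical_partners(scheme: ScoringScheme = DEFAULT_SCHEME) -> dict[str, list[str]]:
    """Residue -> distinct residues with substitution score <= 0."""
    out: dict[str, list[str]] = {}
    for a in ALPHABET[:20]:
        out[a] = [b for b in ALPHABET[:20] if b != a and scheme.score(a, b) <= 0]
    return out


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Per-codon-site substitution probabilities for a homolog pair.

    expected identical match ratio = p_identical / (p_identical + p_conservative).
    Indels insert or delete whole codons, keeping reading frames intact.
    """

    p_identical: float
    p_conservative: float
    p_radical: float
    indel_rate: float = 0.0
    length_codons: int = 300

    def __post_init__(self):
        probs = (self.p_identical, self.p_conservative, self.p_radical)
        if any(p < 0 for p in probs) or self.indel_rate < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("p_identical + p_conservative + p_radical must be 1")
        if self.length_codons < 30:
            raise ValueError("length_codons must be >= 30")

    @property
    def expected_ratio(self) -> float:
        denom = self.p_identical + self.p_conservative
        if denom == 0:
            raise ValueError("expected ratio undefined when p_identical + p_conservative = 0")
        return self.p_identical / denom


@dataclass
class SiteEvent:
    """One codon site of a simulated homolog pair (the generator's log)."""

    kind: str            # identical | conservative | radical | insertion | deletion
    aa_query: str | None
    aa_subject: str | None


@dataclass
class SyntheticTruth:
    """Planted parameters recorded alongside generated inputs."""

    site_logs: dict[str, list[SiteEvent]] = field(default_factory=dict)
    spectra: dict[str, SubstitutionSpectrum] = field(default_factory=dict)
    function_of_gene: dict[str, str] = field(default_factory=dict)
    category_of_function: dict[str, str] = field(default_factory=dict)
    high_substitution_functions: set[str] = field(default_factory=set)
    presence: dict[tuple[str, str], bool] = field(default_factory=dict)
    cluster_of_est: dict[str, str] = field(default_factory=dict)
    cluster_sizes: dict[str, int] = field(default_factory=dict)

    def expected_ratio_from_log(self, gene_id: str) -> float:
        """Observed i/(i+h) over the logged substitution sites of a pair."""
        i = sum(1 for e in self.site_logs[gene_id] if e.kind == "identical")
        h = sum(1 for e in self.site_logs[gene_id] if e.kind == "conservative")
        if i + h == 0:
            raise ValueError(f"{gene_id}: no identical/conservative sites logged")
        return i / (i + h)


# residues eligible as ancestral states at substitutable sites: those with
# at least one conservative partner (C, G and P have none under BLOSUM62)
def true_alignment_from_log(log: list[SiteEvent]) -> tuple[str, str]:
    """Reconstruct the generating (true) peptide alignment of a pair.

    Substitution sites become residue-pair columns; insertions a gap in the
    query row; deletions a gap in the subject row.  This is the internal
    oracle: classifying these columns must reproduce the logged event
    counts without any re-alignment.
    """
    q_row = []
    s_row = []
    for event in log:
        q_row.append(event.aa_query if event.aa_query else "-")
        s_row.append(event.aa_subject if event.aa_subject else "-")
    return "".join(q_row), "".join(s_row)


def _ancestral_pool(scheme: ScoringScheme) -> list[str]:
    partners = conservative_partners(scheme)
    return sorted(a for a, p in partners.items() if p)


def _random_codon(rng: np.random.Generator, aa: str) -> str:
    codons = _CODONS[aa]
    return codons[rng.integers(len(codons))]


def simulate_homolog_pair(
    spectrum: SubstitutionSpectrum,
    seed: int | np.random.Generator,
    gene_id: str = "gene",
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[SequenceRecord, SequenceRecord, float, list[SiteEvent]]:
    """Simulate an in-frame coding-sequence pair under a substitution spectrum.

    Per codon site the subject keeps the query amino acid (identical),
    replaces it by a uniformly chosen residue with positive BLOSUM62 score
    (conservative) or by one with score <= 0 (radical); codons are uniform
    among synonyms, so no internal stop codons can arise.  Returns the two
    records, the spectrum's expected identical match ratio and the per-site
    event log.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = _ancestral_pool(scheme)
    cons = conservative_partners(scheme)
    rad = radical_partners(scheme)
    q_codons: list[str] = []
    s_codons: list[str] = []
    log: list[SiteEvent] = []
    for _ in range(spectrum.length_codons):
        aa = pool[rng.integers(len(pool))]
        if spectrum.indel_rate > 0 and rng.random() < spectrum.indel_rate:
            # whole-codon indel: coin-flip between insertion (subject gains
            # a codon) and deletion (subject loses this codon)
            if rng.random() < 0.5:
                extra = pool[rng.integers(len(pool))]
                s_codons.append(_random_codon(rng, extra))
                log.append(SiteEvent("insertion", None, extra))
            else:
                q_codons.append(_random_codon(rng, aa))
                log.append(SiteEvent("deletion", aa, None))
                continue
        u = rng.random()
        if u < spectrum.p_identical:
            kind, aa_s = "identical", aa
        elif u < spectrum.p_identical + spectrum.p_conservative:
            partners = cons[aa]
            if not partners:
                raise AssertionError(
                    f"residue {aa} has no conservative BLOSUM62 partner")
            kind, aa_s = "conservative", partners[rng.integers(len(partners))]
        else:
            partners = rad[aa]
            if not partners:
                raise AssertionError(
                    f"residue {aa} has no radical BLOSUM62 partner")
            kind, aa_s = "radical", partners[rng.integers(len(partners))]
        q_codons.append(_random_codon(rng, aa))
        s_codons.append(_random_codon(rng, aa_s))
        log.append(SiteEvent(kind, aa, aa_s))
    query = SequenceRecord(f"{gene_id}|q", "".join(q_codons))
    subject = SequenceRecord(f"{gene_id}|s", "".join(s_codons))
    return query, subject, spectrum.expected_ratio, log


def simulate_function_panel(
    n_genes_per_function: int,
    spectra_by_function: dict[str, SubstitutionSpectrum],
    seed: int,
    categories: dict[str, str] | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
):
    """Gene pairs drawn per functional class, each from its own spectrum.

    Returns (query records, subject records, annotation rows, truth).  The
    truth labels functions as high- vs low-substitution by their expected
    identical match ratio (lower ratio = higher substitution flexibility).
    """
    if len(spectra_by_function) < 2:
        raise ValueError("need at least 2 functions with distinct spectra")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    queries: list[SequenceRecord] = []
    subjects: list[SequenceRecord] = []
    annotation_rows: list[dict] = []
    median_ratio = float(np.median(
        [sp.expected_ratio for sp in spectra_by_function.values()]))
    for func in sorted(spectra_by_function):
        spectrum = spectra_by_function[func]
        category = (categories or {}).get(func, func)
        truth.category_of_function[func] = category
        if spectrum.expected_ratio < median_ratio:
            truth.high_substitution_functions.add(func)
        for g in range(n_genes_per_function):
            gene_id = f"{func}_{g:03d}"
            q, s, _, log = simulate_homolog_pair(spectrum, rng, gene_id, scheme)
            queries.append(q)
            subjects.append(s)
            truth.site_logs[gene_id] = log
            truth.spectra[gene_id] = spectrum
            truth.function_of_gene[gene_id] = func
            annotation_rows.append({
                "gene_id": q.id, "function": func, "category": category,
                "evalue": 1e-50,
            })
    return queries, subjects, annotation_rows, truth


def _random_coding_sequence(rng: np.random.Generator, n_codons: int,
                            scheme: ScoringScheme = DEFAULT_SCHEME) -> str:
    pool = _ancestral_pool(scheme)
    return "".join(_random_codon(rng, pool[rng.integers(len(pool))])
                   for _ in range(n_codons))


def simulate_target_datasets(
    gene_set: list[SequenceRecord],
    presence_plan: dict[str, set[str] | list[str]],
    decoy_count: int,
    seed: int,
    spectrum: SubstitutionSpectrum | None = None,
    genome_like: set[str] | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[dict[str, list[SequenceRecord]], SyntheticTruth]:
    """Build per-dataset sequence collections from a presence/absence plan.

    Present genes appear as spectrum-mutated homologs; absent genes are
    simply missing; decoys are unrelated random coding sequences.  Datasets
    named in ``genome_like`` emulate fragmented genome assemblies: each
    homolog is split into >= 2 exon-like pieces joined by random spacer.
    """
    known = {g.id for g in gene_set}
    for dataset, genes in presence_plan.items():
        unknown = set(genes) - known
        if unknown:
            raise ValueError(
                f"presence plan for {dataset!r} references unknown gene(s) "
                f"{sorted(unknown)}")
    rng = np.random.default_rng(seed)
    spectrum = spectrum or SubstitutionSpectrum(0.85, 0.10, 0.05, length_codons=30)
    truth = SyntheticTruth()
    datasets: dict[str, list[SequenceRecord]] = {}
    for dataset in sorted(presence_plan):
        present = set(presence_plan[dataset])
        records: list[SequenceRecord] = []
        for gene in gene_set:
            truth.presence[(gene.id, dataset)] = gene.id in present
            if gene.id not in present:
                continue
            n_codons = len(gene.seq) // 3
            spec = SubstitutionSpectrum(
                spectrum.p_identical, spectrum.p_conservative,
                spectrum.p_radical, spectrum.indel_rate,
                max(30, n_codons))
            # re-evolve the gene itself codon-by-codon so the homolog is a
            # mutated copy, not an unrelated draw
            homolog = _mutate_coding(rng, gene.seq, spec, scheme)
            if genome_like and dataset in genome_like:
                n_frag = 2 + int(rng.integers(0, 2))
                cut_points = sorted(
                    rng.choice(np.arange(3, len(homolog) - 3, 3),
                               size=n_frag - 1, replace=False))
                pieces = np.split(np.frombuffer(homolog.encode(), dtype="S1"),
                                  cut_points)
                spaced = []
                for piece in pieces:
                    spaced.append(piece.tobytes().decode())
                    spaced.append(_random_spacer(rng, int(rng.integers(30, 90))))
                homolog = "".join(spaced[:-1])
            records.append(SequenceRecord(f"{dataset}|{gene.id}", homolog))
        for d in range(decoy_count):
            records.append(SequenceRecord(
                f"{dataset}|decoy_{d:03d}",
                _random_coding_sequence(rng, 100, scheme)))
        datasets[dataset] = records
    return datasets, truth


def _mutate_coding(rng: np.random.Generator, seq: str,
                   spectrum: SubstitutionSpectrum,
                   scheme: ScoringScheme) -> str:
    cons = conservative_partners(scheme)
    rad = radical_partners(scheme)
    out: list[str] = []
    for k in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[k:k + 3]
        aa = _AA_BY_CODON.get(codon, None)
        if aa is None or aa == "*":
            out.append(codon)
            continue
        u = rng.random()
        if u < spectrum.p_identical:
            out.append(codon)
        elif u < spectrum.p_identical + spectrum.p_conservative and cons[aa]:
            out.append(_random_codon(rng, cons[aa][rng.integers(len(cons[aa]))]))
        else:
            out.append(_random_codon(rng, rad[aa][rng.integers(len(rad[aa]))]))
    out.append(seq[len(seq) - len(seq) % 3:])
    return "".join(out)


def _random_spacer(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


def simulate_est_collection(
    n_clusters: int,
    size_distribution,
    seed: int,
    exemplar_len: int = 400,
    mutation_rate: float = 0.01,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """An EST collection of near-identical copies of cluster exemplars.

    ``size_distribution`` is either a sequence of per-cluster sizes or a
    callable rng -> size.  Each EST is its exemplar with at most 1% of
    bases substituted; the truth records every EST's cluster.  Output is
    deterministic given the seed.
    """
    if mutation_rate > 0.01:
        raise ValueError("ESTs must stay within 1% of their exemplar")
    rng = np.random.default_rng(seed)
    if callable(size_distribution):
        sizes = [int(size_distribution(rng)) for _ in range(n_clusters)]
    else:
        sizes = [int(s) for s in size_distribution]
        if len(sizes) != n_clusters:
            raise ValueError("one size per cluster required")
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    truth = SyntheticTruth()
    records: list[SequenceRecord] = []
    for c, size in enumerate(sizes):
        cluster_id = f"cl{c:04d}"
        truth.cluster_sizes[cluster_id] = size
        exemplar = "".join("ACGT"[b] for b in rng.integers(0, 4, size=exemplar_len))
        for e in range(size):
            bases = list(exemplar)
            n_mut = min(rng.binomial(exemplar_len, mutation_rate),
                        int(mutation_rate * exemplar_len))
            for pos in rng.choice(exemplar_len, size=n_mut, replace=False):
                bases[pos] = "ACGT"[(("ACGT".index(bases[pos])) +
                                     1 + int(rng.integers(3))) % 4]
            est_id = f"{cluster_id}_est{e:04d}"
            records.append(SequenceRecord(est_id, "".join(bases)))
            truth.cluster_of_est[est_id] = cluster_id
    return records, truth
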