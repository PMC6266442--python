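"""Synthetic phage data with exact ground truth.

The genome generator emulates a small lytic myophage genome: ~50 kb, ~80
unidirectional ORFs with planted Shine–Dalgarno cores upstream of
ATG/GTG/TTG starts, GC near 44%. Every generator is deterministic under a
fixed seed and returns its ground truth alongside the data.

Ground truth is kept *exact* by a repair loop: after assembly the genome
is annotated with the same filter that downstream analyses use, and any
unplanned filter-passing candidate (a "decoy" arising by chance in another
frame or on the reverse strand) is disrupted — by a direct base edit in
free intergenic sequence, or by a codon substitution inside a planted gene
(synonymous where possible, any sense codon as a fallback; the planted
frame never gains a stop and planted coordinates/SDs are never touched).
A per-position memory forbids reverting a base to an abandoned value, so
repairs cannot cycle. The loop re-annotates until the candidate set equals
the planted truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from .genome import GenomeRecord, FeatureTable
from .orfs import (
    SD_CORE,
    START_CODONS,
    STOP_CODONS,
    OrfCandidate,
    SDParams,
    annotate_genome,
    find_orfs,
)
from .phenotype import GrowthCurve, SpotTestRecord, SCORE_ORDER

__all__ = [
    "GenomeSpec",
    "GrowthSpec",
    "ST32LIKE_GENOME",
    "GROWTH_PRESETS",
    "simulate_genome",
    "diverge_proteome",
    "simulate_growth_curve",
    "simulate_spot_matrix",
]

_BASES = "ACGT"
_SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]
_CODON_AA = {c: str(Seq(c).translate(table=11)) for c in _SENSE_CODONS}
_SYNONYMS: dict[str, list[str]] = {}
for _c, _aa in _CODON_AA.items():
    _SYNONYMS.setdefault(_aa, []).append(_c)


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic phage-like genome."""

    n_orfs: int = 80
    orf_len_aa: tuple[int, int] = (45, 650)  # log-uniform range, residues
    gc_target: float = 44.0
    sd_rate: float = 1.0
    intergenic_len: tuple[int, int] = (30, 120)
    start_codon_probs: tuple[float, float, float] = (0.81, 0.114, 0.076)
    sd_spacer: tuple[int, int] = (4, 9)
    min_aa: int = 45
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.start_codon_probs) - 1.0) > 1e-6:
            raise ValueError("start-codon probabilities must sum to 1")
        if not 0.0 < self.gc_target < 100.0:
            raise ValueError("gc_target must be in (0, 100)")
        if self.intergenic_len[0] < self.sd_spacer[1] + len(SD_CORE) + 3:
            raise ValueError("intergenic spacers too short to host an SD core")


ST32LIKE_GENOME = GenomeSpec()


@dataclass(frozen=True)
class GrowthSpec:
    """One-step growth-curve simulation: adsorption, latency, synchronized burst."""

    latent_min: float
    burst: float
    temperature_C: float = 37.0
    initial_free_phage: float = 2e5  # PFU/mL after the adsorption wash
    lysis_spread_min: float = 6.0  # SD of per-cell lysis times (truncated at 0)
    sampling_times: tuple = tuple(range(0, 130, 10))
    replicates: int = 3
    moi: float = 0.05
    noise: str = "poisson"  # plate-count noise, rescaled by dilution
    plate_volume_ml: float = 0.1
    seed: int = 0


# Burst/latent regimes measured for the reference phage at three temperatures.
GROWTH_PRESETS = {
    "37C": GrowthSpec(latent_min=55.0, burst=2.0, temperature_C=37.0),
    "30C": GrowthSpec(latent_min=54.0, burst=64.0, temperature_C=30.0),
    "20C": GrowthSpec(
        latent_min=102.0, burst=602.0, temperature_C=20.0,
        lysis_spread_min=10.0, sampling_times=tuple(range(0, 210, 10)),
    ),
}


def _random_bases(rng, n: int, gc: float) -> list[str]:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]  # A C G T
    return ["ACGT"[i] for i in rng.choice(4, size=int(n), p=probs)]


def _random_sense_codon(rng, gc: float, exclude_aa: str | None = None) -> str:
    p_gc = gc / 100.0
    pb = {"A": (1 - p_gc) / 2, "C": p_gc / 2, "G": p_gc / 2, "T": (1 - p_gc) / 2}
    codons = [c for c in _SENSE_CODONS if exclude_aa is None or _CODON_AA[c] != exclude_aa]
    w = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in codons])
    return codons[rng.choice(len(codons), p=w / w.sum())]


def _build_genome(spec: GenomeSpec, rng) -> tuple[list[str], list[dict]]:
    """Assemble sequence pieces and per-gene layout records."""
    seq: list[str] = []
    genes: list[dict] = []
    log_lo, log_hi = np.log(spec.orf_len_aa[0]), np.log(spec.orf_len_aa[1])

    def add_intergenic(n: int):
        seq.extend(_random_bases(rng, n, spec.gc_target))

    add_intergenic(rng.integers(spec.intergenic_len[0], spec.intergenic_len[1] + 1))
    for gi in range(spec.n_orfs):
        has_sd = rng.random() < spec.sd_rate
        spacer = int(rng.integers(spec.sd_spacer[0], spec.sd_spacer[1] + 1))
        if has_sd:
            # overwrite the tail of the intergenic run with SD core + spacer
            needed = len(SD_CORE) + spacer
            core_start = len(seq) - needed
            seq[core_start : core_start + len(SD_CORE)] = list(SD_CORE)
            sd_interval = (core_start, core_start + len(SD_CORE))
        else:
            sd_interval = None
        aa_len = int(round(np.exp(rng.uniform(log_lo, log_hi))))
        aa_len = max(spec.min_aa, aa_len)
        start_codon = rng.choice(START_CODONS, p=spec.start_codon_probs)
        gene_start = len(seq)
        seq.extend(start_codon)
        for _ in range(aa_len - 1):
            seq.extend(_random_sense_codon(rng, spec.gc_target))
        seq.extend(rng.choice(STOP_CODONS))
        genes.append(
            {
                "id": f"gene{gi + 1}",
                "start0": gene_start,
                "end0": len(seq),  # half-open
                "start_codon": str(start_codon),
                "sd_interval": sd_interval,
                "has_sd": has_sd,
            }
        )
        add_intergenic(rng.integers(spec.intergenic_len[0], spec.intergenic_len[1] + 1))
    return seq, genes


def _protected_positions(genes: list[dict]) -> set[int]:
    """Positions that repair edits must not touch directly: SD cores, planted
    start and stop codons. (Gene interiors are guarded separately by the
    synonymous-substitution rule.)"""
    prot: set[int] = set()
    for g in genes:
        if g["sd_interval"]:
            prot.update(range(*g["sd_interval"]))
        prot.update(range(g["start0"], g["start0"] + 3))
        prot.update(range(g["end0"] - 3, g["end0"]))
    return prot


def _gene_at(genes: list[dict], pos: int) -> dict | None:
    for g in genes:
        if g["start0"] <= pos < g["end0"]:
            return g
    return None


def _apply_edits(seq, edits: dict[int, str], forbidden: dict[int, set]) -> bool:
    """Apply base edits unless any would revert a base to a previous value.

    The per-position memory of abandoned bases breaks repair cycles where
    fixing one decoy would exactly undo the fix of another.
    """
    for p, b in edits.items():
        if b in forbidden.get(p, ()):
            return False
    for p, b in edits.items():
        forbidden.setdefault(p, set()).add(seq[p])
        seq[p] = b
    return True


def _try_direct_edit(seq, positions_needed, protected, genes, forbidden) -> bool:
    """Apply base edits at free positions only (not protected, not in a gene)."""
    for p in positions_needed:
        if p in protected or _gene_at(genes, p) is not None:
            return False
    return _apply_edits(seq, positions_needed, forbidden)


def _try_gene_edit(
    seq, genes, window: tuple[int, int, str], want_stop: bool, rng, forbidden,
    synonymous_only: bool = True,
) -> bool:
    """Make the decoy codon at genome positions ``window`` a stop (or break a
    start) by a codon substitution in an overlapping planted gene.

    Substitutions are always sense codons (the planted frame stays stop-free
    and the planted coordinates untouched); synonymous ones are preferred,
    but any sense codon is allowed as a fallback — the planted gene's
    protein simply changes, which the ground truth (coordinates + SD)
    tolerates.
    """
    w0, strand = window[0], window[2]
    for g in genes:
        for off in range(3):
            pos = w0 + off
            if not (g["start0"] + 3 <= pos < g["end0"] - 3):
                continue  # only interior codons of the planted gene
            ci = (pos - g["start0"]) // 3
            c0 = g["start0"] + 3 * ci
            current = "".join(seq[c0 : c0 + 3])
            aa = _CODON_AA.get(current)
            if aa is None:
                continue
            alts = list(_SYNONYMS[aa]) if synonymous_only else list(_SENSE_CODONS)
            rng.shuffle(alts)
            for alt in alts:
                if alt == current:
                    continue
                trial = seq[c0:c0 + 3]
                seq[c0:c0 + 3] = list(alt)
                codon = "".join(seq[w0 : w0 + 3])
                if strand == "-":
                    codon = str(Seq(codon).reverse_complement())
                ok = codon in STOP_CODONS if want_stop else codon not in START_CODONS
                seq[c0:c0 + 3] = trial
                if ok:
                    edits = {c0 + i: alt[i] for i in range(3) if trial[i] != alt[i]}
                    if _apply_edits(seq, edits, forbidden):
                        return True
    return False


def _disrupt(seq, genes, protected, cand: OrfCandidate, rng, min_aa: int, forbidden) -> bool:
    """Disrupt one decoy candidate; returns True if an edit was applied.

    Prefers planting an in-frame stop within the decoy's first ``min_aa``
    codons so that the residual start→stop span is too short to pass the
    filter. Edit choices are randomized to avoid deterministic cycles
    (an edit can spawn a new decoy that a later round must handle).
    """
    s0, e0 = cand.start - 1, cand.end  # half-open genome coords
    # Codon windows of the decoy in genome coordinates, gene orientation.
    if cand.strand == "+":
        windows = [(p, p + 3, "+") for p in range(s0, e0 - 3, 3)]
        start_window = (s0, s0 + 3, "+")
    else:
        windows = [(p, p + 3, "-") for p in range(e0 - 3, s0 + 2, -3)]
        start_window = (e0 - 3, e0, "-")
    internal = windows[1:]
    early = internal[:min_aa]
    late = internal[min_aa:]

    def try_stop(wins) -> bool:
        wins = list(wins)
        rng.shuffle(wins)
        for w in wins:
            current = "".join(seq[w[0] : w[1]])
            stops = list(STOP_CODONS)
            rng.shuffle(stops)
            for stop in stops:
                target = stop if w[2] == "+" else str(Seq(stop).reverse_complement())
                edits = {w[0] + i: target[i] for i in range(3) if current[i] != target[i]}
                if edits and _try_direct_edit(seq, edits, protected, genes, forbidden):
                    return True
        return False

    def try_break_start() -> bool:
        w0, w1, strand = start_window
        current = "".join(seq[w0:w1])
        order = list(range(3))
        rng.shuffle(order)
        for i in order:
            if w0 + i in protected or _gene_at(genes, w0 + i) is not None:
                continue
            bases = list(_BASES)
            rng.shuffle(bases)
            for b in bases:
                if b == current[i]:
                    continue
                codon = current[:i] + b + current[i + 1:]
                oriented = codon if strand == "+" else str(Seq(codon).reverse_complement())
                if oriented not in START_CODONS and _apply_edits(
                    seq, {w0 + i: b}, forbidden
                ):
                    return True
        return False

    if try_stop(early):
        return True
    for w in early:
        if _try_gene_edit(seq, genes, w, want_stop=True, rng=rng, forbidden=forbidden):
            return True
    if try_break_start():
        return True
    if try_stop(late):
        return True
    for w in late:
        if _try_gene_edit(seq, genes, w, want_stop=True, rng=rng, forbidden=forbidden):
            return True
    if _try_gene_edit(seq, genes, start_window, want_stop=False, rng=rng, forbidden=forbidden):
        return True
    # last resort: non-synonymous (still sense-codon) substitutions
    for w in early + late:
        if _try_gene_edit(seq, genes, w, want_stop=True, rng=rng, forbidden=forbidden,
                          synonymous_only=False):
            return True
    return _try_gene_edit(
        seq, genes, start_window, want_stop=False, rng=rng, forbidden=forbidden,
        synonymous_only=False,
    )


def simulate_genome(
    spec: GenomeSpec = ST32LIKE_GENOME,
    sd_params: SDParams = SDParams(),
    max_repair_rounds: int = 300,
) -> tuple[GenomeRecord, FeatureTable]:
    """Generate a genome and its exact ground-truth feature table.

    The returned truth table contains exactly the planted SD-bearing genes;
    annotating the genome with the same parameters recovers it exactly.
    """
    rng = np.random.default_rng(spec.seed)
    seq, genes = _build_genome(spec, rng)
    protected = _protected_positions(genes)
    truth_keys = {
        (g["start0"] + 1, g["end0"], "+") for g in genes if g["has_sd"]
    }
    gid = f"synthetic_phage_seed{spec.seed}"
    truth_stops = {(e, st) for (_, e, st) in truth_keys}
    forbidden: dict[int, set] = {}
    for _ in range(max_repair_rounds):
        genome = GenomeRecord(gid, "".join(seq))
        called = annotate_genome(
            genome, min_aa=spec.min_aa, strands="both", require_sd=True,
            sd_params=sd_params,
        )
        extras = [c for c in called if (c.start, c.end, c.strand) not in truth_keys]
        # A planted gene can be *shadowed* by a longer SD-less ORF sharing its
        # stop (an in-frame upstream start): it is then neither called nor an
        # extra, so hunt shadows among the raw calls as well.
        raw = find_orfs(genome, min_aa=spec.min_aa, strands="both")
        shadows = [
            c for c in raw
            if (c.end, c.strand) in truth_stops
            and (c.start, c.end, c.strand) not in truth_keys
        ]
        if not extras and not shadows and len(called) == len(truth_keys):
            break
        fixed_any = False
        for cand in extras + shadows:
            if _disrupt(seq, genes, protected, cand, rng, spec.min_aa, forbidden):
                fixed_any = True
        if not fixed_any:
            raise RuntimeError(
                f"could not repair {len(extras) + len(shadows)} decoy ORF(s); "
                "spec infeasible"
            )
    else:
        raise RuntimeError("ground-truth repair did not converge")

    genome = GenomeRecord(gid, "".join(seq))
    rows = []
    for g in genes:
        if not g["has_sd"]:
            continue
        rows.append(
            OrfCandidate(
                start=g["start0"] + 1,
                end=g["end0"],
                strand="+",
                start_codon=g["start_codon"],
                id=g["id"],
            )
        )
    return genome, FeatureTable(genome_id=gid, rows=rows)


def diverge_proteome(
    table: FeatureTable,
    genome: GenomeRecord,
    target_identity: float,
    seed: int = 0,
) -> tuple[GenomeRecord, dict[str, float]]:
    """Codon-level divergence of every encoded protein toward a target identity.

    For each gene, ``round((1 - t/100) * L)`` interior residues are replaced
    by different amino acids via whole-codon substitutions, so the realized
    identity to the parent protein is exactly ``(L - m) / L``. Returns the
    mutated genome and the realized identities (percent) per gene id.
    """
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    realized: dict[str, float] = {}
    for row in table.rows:
        if row.strand != "+":
            raise ValueError("diverge_proteome expects unidirectional (+) genes")
        L = row.size_aa
        m = int(round((1.0 - target_identity / 100.0) * L))
        m = min(m, L - 1)
        positions = rng.choice(np.arange(1, L), size=m, replace=False) if m else []
        for ci in positions:
            c0 = (row.start - 1) + 3 * int(ci)
            current = "".join(seq[c0 : c0 + 3])
            aa = _CODON_AA[current]
            seq[c0 : c0 + 3] = list(_random_sense_codon(rng, 50.0, exclude_aa=aa))
        realized[row.id] = 100.0 * (L - m) / L
    return GenomeRecord(genome.id + "_diverged", "".join(seq)), realized


def simulate_growth_curve(spec: GrowthSpec) -> GrowthCurve:
    """One-step growth curve: plateau, normally-spread synchronized lysis, plateau.

    The expected titer is ``N0 * (1 + burst * F(t))`` where F is the
    (0-truncated) Gaussian CDF of per-cell lysis times. ``latent_min`` is
    planted as the *mid-exponential time of the log10 titer curve* — the
    quantity the latent-period estimator is defined to read off — so the
    lysis-time centre sits at ``latent - spread * z_p`` with
    ``p = (sqrt(1+burst) - 1) / burst`` (the lysed fraction at which the
    log curve is halfway up). Poisson plate-count noise is applied at a
    dilution chosen to keep ~200 countable plaques, then rescaled —
    mimicking double-layer titration.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_times, dtype=float)
    from scipy.stats import norm

    p_half = (np.sqrt(1.0 + spec.burst) - 1.0) / spec.burst if spec.burst > 0 else 0.5
    center = spec.latent_min - spec.lysis_spread_min * norm.ppf(p_half)
    if spec.lysis_spread_min <= 0:
        frac = (t >= spec.latent_min).astype(float)
    else:
        z = norm.cdf((t - center) / spec.lysis_spread_min)
        z0 = norm.cdf(-center / spec.lysis_spread_min)
        frac = (z - z0) / (1.0 - z0)  # truncate lysis times at t=0
    expected = spec.initial_free_phage * (1.0 + spec.burst * frac)
    titers = np.empty((spec.replicates, t.size))
    for r in range(spec.replicates):
        if spec.noise == "none":
            titers[r] = expected
            continue
        for j, e in enumerate(expected):
            raw = e * spec.plate_volume_ml
            k = max(0, int(np.floor(np.log10(max(raw, 1.0) / 200.0))))
            factor = 10.0 ** k
            count = rng.poisson(raw / factor)
            titers[r, j] = max(count, 1) * factor / spec.plate_volume_ml
    return GrowthCurve(
        temperature_C=spec.temperature_C,
        moi=spec.moi,
        times_min=t,
        titers=titers,
    )


def simulate_spot_matrix(
    n_strains: int,
    susceptibility_profile: dict[str, int],
    seed: int = 0,
    pathogenic_fraction: float = 0.5,
) -> list[SpotTestRecord]:
    """Spot-test records with prefix-monotone infectivity patterns.

    ``susceptibility_profile`` maps score symbols to strain counts; any
    remainder up to ``n_strains`` is resistant ("-"). Strain order and
    pathogenicity assignment are shuffled deterministically by seed.
    """
    bad = set(susceptibility_profile) - set(SCORE_ORDER)
    if bad:
        raise ValueError(f"unknown score symbols in profile: {sorted(bad)}")
    total = sum(susceptibility_profile.values())
    if total > n_strains:
        raise ValueError("profile assigns more strains than n_strains")
    rng = np.random.default_rng(seed)
    scores = [s for s, k in susceptibility_profile.items() for _ in range(k)]
    scores += ["-"] * (n_strains - total)
    rng.shuffle(scores)
    n_path = int(round(pathogenic_fraction * n_strains))
    pathogenic = np.array([True] * n_path + [False] * (n_strains - n_path))
    rng.shuffle(pathogenic)
    return [
        SpotTestRecord.from_score(f"strain{i + 1:03d}", bool(pathogenic[i]), s)
        for i, s in enumerate(scores)
    ]
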