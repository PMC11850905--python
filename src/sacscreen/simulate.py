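"""Synthetic-data generators with known ground truth for every pipeline input.

Four generators, each bit-reproducible given (config, seed) and each
returning a ledger that fully determines the expected output of the
deterministic stages downstream:

* a random sgRNA library (unique 20-mers, guide ids encoding gene membership);
* a paired negative-binomial screen count matrix with planted resistance
  genes (variance mu + phi*mu^2; a shared per-replicate log-normal depth
  factor creates the pairing);
* read-level FASTQ with the screen's read layout: 6-nt sample barcode,
  random stuffer, key sequence at a variable offset, optional extra G, the
  20-nt guide, random tail;
* a DepMap-like cell-line panel with a planted gene -> drug-class effect and
  optional aneuploidy mediation structure; and per-condition mitotic-event
  tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ReadRecord, SampleSheet, SgRNALibrary
from .quant import DEFAULT_KEY, DEFAULT_WINDOW, extract_candidates, find_key

BASES = np.array(list("ACGT"))


# -- library -----------------------------------------------------------------

def make_library(n_genes: int, guides_per_gene: int, seed: int) -> SgRNALibrary:
    """Random guide library: unique 20-mers, ``GENE####_g#`` guide ids."""
    if n_genes <= 0 or guides_per_gene <= 0:
        raise ValueError("n_genes and guides_per_gene must be positive")
    rng = np.random.default_rng(seed)
    n = n_genes * guides_per_gene
    seqs: list[str] = []
    seen: set[str] = set()
    for _ in range(100):  # bounded retry on (vanishingly unlikely) collisions
        draw = rng.integers(0, 4, size=(n - len(seqs), 20))
        for row in draw:
            s = "".join(BASES[row])
            if s not in seen:
                seen.add(s)
                seqs.append(s)
        if len(seqs) == n:
            break
    else:
        raise RuntimeError("could not draw enough unique 20-mers")
    gene_ids = [f"GENE{g:04d}" for g in range(n_genes) for _ in range(guides_per_gene)]
    guide_ids = [
        f"GENE{g:04d}_g{i}" for g in range(n_genes) for i in range(guides_per_gene)
    ]
    return SgRNALibrary(guide_ids=guide_ids, gene_ids=gene_ids, sequences=seqs)


# -- screen counts -----------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Paired screen simulation settings.

    depth_per_guide is the expected control count per guide; nb_dispersion
    is phi in var = mu + phi*mu^2 (0 switches noise off entirely, leaving
    the rounded means); planted maps gene_id -> log2 effect on treated
    counts; replicate_sd is the sd of the shared per-replicate log-normal
    depth factor that induces the pairing.
    """

    n_replicates: int = 2
    depth_per_guide: float = 500.0
    nb_dispersion: float = 0.1
    planted: dict[str, float] = field(default_factory=dict)
    replicate_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates <= 0 or self.depth_per_guide <= 0:
            raise ValueError("n_replicates and depth_per_guide must be positive")
        if self.nb_dispersion < 0 or self.replicate_sd < 0:
            raise ValueError("nb_dispersion and replicate_sd must be >= 0")


def _nb_sample(rng, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial draw, mean mu, variance mu + phi*mu^2 (gamma-Poisson);
    phi = 0 returns the rounded means (noise off)."""
    if phi == 0:
        return np.rint(mu).astype(int)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def simulate_counts(
    library: SgRNALibrary, config: ScreenSimConfig
) -> tuple[pd.DataFrame, dict]:
    """Simulate a paired control/treated count matrix over a library.

    Samples are named ``control_r<i>`` / ``treated_r<i>``. Control means are
    depth * replicate factor; treated means additionally scale guides of
    planted genes by 2**effect. The ledger records the per-replicate
    factors, per-sample means and planted effects.
    """
    rng = np.random.default_rng(config.seed)
    n = len(library)
    effect = np.array(
        [2.0 ** config.planted.get(g, 0.0) for g in library.gene_ids]
    )
    rep_factors = np.exp(rng.normal(0.0, config.replicate_sd, size=config.n_replicates))
    counts: dict[str, np.ndarray] = {}
    means: dict[str, np.ndarray] = {}
    for i, f in enumerate(rep_factors, start=1):
        mu_c = np.full(n, config.depth_per_guide) * f
        mu_t = mu_c * effect
        counts[f"control_r{i}"] = _nb_sample(rng, mu_c, config.nb_dispersion)
        counts[f"treated_r{i}"] = _nb_sample(rng, mu_t, config.nb_dispersion)
        means[f"control_r{i}"] = mu_c
        means[f"treated_r{i}"] = mu_t
    matrix = pd.DataFrame(counts, index=pd.Index(library.guide_ids, name="guide_id"))
    ledger = {
        "planted": dict(config.planted),
        "replicate_factors": rep_factors.tolist(),
        "means": {s: m.tolist() for s, m in means.items()},
        "seed": config.seed,
    }
    return matrix, ledger


def screen_design_frame(n_replicates: int) -> pd.DataFrame:
    """Design table matching :func:`simulate_counts` sample naming."""
    rows = []
    for i in range(1, n_replicates + 1):
        rows.append((f"control_r{i}", "control", f"r{i}"))
        rows.append((f"treated_r{i}", "treated", f"r{i}"))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"])


# -- read-level FASTQ --------------------------------------------------------

@dataclass
class ReadSimConfig:
    """Read layout settings for FASTQ simulation.

    offset_range is the inclusive 1-based range of the key's first base
    (matching the extractor's search window); g_insertion_prob is the chance
    of the extra G between key and guide.
    """

    read_length: int = 75
    key: str = DEFAULT_KEY
    offset_range: tuple[int, int] = DEFAULT_WINDOW
    g_insertion_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.offset_range
        if lo < 7:
            raise ValueError("key cannot start before the 6-nt barcode ends")
        # worst case: key at hi, extra G, 20-nt guide must fit the read
        if hi + len(self.key) + 1 + 20 - 1 > self.read_length:
            raise ValueError(
                f"layout does not fit read_length={self.read_length}: key at "
                f"{hi} + G + 20-nt guide needs {hi + len(self.key) + 20}"
            )
        if not 0 <= self.g_insertion_prob <= 1:
            raise ValueError("g_insertion_prob must be in [0, 1]")


def _random_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)]) if n > 0 else ""


def simulate_reads(
    counts_col: pd.Series,
    library: SgRNALibrary,
    barcode: str,
    config: ReadSimConfig,
    sample_id: str = "S",
) -> tuple[list[ReadRecord], dict]:
    """Emit exactly counts[g] reads per guide g with the screen read layout.

    Each read is barcode + random stuffer + key + (G with probability
    g_insertion_prob) + guide + random tail, qualities constant 'I'. Reads
    are rejection-resampled (bounded retries) so the random flanks never
    create an earlier in-window key occurrence or an ambiguous library
    match — the generated FASTQ therefore round-trips bit-exactly through
    the extractor. The ledger records every read's guide and key offset.
    """
    rng = np.random.default_rng(config.seed)
    seq_to_guide = library.seq_to_guide
    guide_seq = dict(zip(library.guide_ids, library.sequences))
    lo, hi = config.offset_range
    reads: list[ReadRecord] = []
    ledger_reads: list[dict] = []
    qual = "I" * config.read_length
    idx = 0
    for guide in counts_col.index:
        count = int(counts_col[guide])
        if count < 0:
            raise ValueError("counts must be non-negative")
        gseq = guide_seq[guide]
        for _ in range(count):
            for _attempt in range(100):
                offset = int(rng.integers(lo, hi + 1))  # 1-based key start
                with_g = rng.random() < config.g_insertion_prob
                stuffer = _random_seq(rng, offset - 1 - len(barcode))
                insert = "G" if with_g else ""
                core = barcode + stuffer + config.key + insert + gseq
                tail = _random_seq(rng, config.read_length - len(core))
                seq = core + tail
                if find_key(seq, key=config.key, window=config.offset_range) != offset:
                    continue  # flank created an earlier key occurrence
                hits = {
                    seq_to_guide[c]
                    for c in extract_candidates(seq, key=config.key, window=config.offset_range)
                    if c in seq_to_guide
                }
                if hits == {guide}:
                    break
            else:
                raise RuntimeError(f"could not build an unambiguous read for {guide}")
            read_id = f"{sample_id}_{guide}_{idx}"
            idx += 1
            reads.append(ReadRecord(read_id=read_id, sequence=seq, quality=qual))
            ledger_reads.append(
                {"read_id": read_id, "guide_id": guide, "key_offset": offset,
                 "g_inserted": bool(with_g)}
            )
    ledger = {"sample_id": sample_id, "barcode": barcode, "reads": ledger_reads,
              "seed": config.seed}
    return reads, ledger


def simulate_screen_fastq(
    counts: pd.DataFrame,
    library: SgRNALibrary,
    sheet: SampleSheet,
    config: ReadSimConfig,
) -> tuple[list[ReadRecord], dict]:
    """FASTQ for a whole count matrix: one pooled read list over all samples
    in the sheet (per-sample seeds derived from the config seed)."""
    sample_to_barcode = {s: b for b, s in sheet.barcode_to_sample.items()}
    all_reads: list[ReadRecord] = []
    ledgers = {}
    for i, sample in enumerate(counts.columns):
        if sample not in sample_to_barcode:
            raise ValueError(f"sample {sample!r} missing from the sample sheet")
        cfg = ReadSimConfig(
            read_length=config.read_length,
            key=config.key,
            offset_range=config.offset_range,
            g_insertion_prob=config.g_insertion_prob,
            seed=(config.seed * 1000 + i) % (2**31),
        )
        reads, ledger = simulate_reads(
            counts[sample], library, sample_to_barcode[sample], cfg, sample_id=sample
        )
        all_reads.extend(reads)
        ledgers[sample] = ledger
    return all_reads, {"samples": ledgers}


# -- cell-line panel ---------------------------------------------------------

@dataclass
class PanelSimConfig:
    """DepMap-like panel simulation settings.

    target_classes maps a drug class name to the planted effect size (in
    response-sd units) linking the target gene to that class's drugs;
    aneuploidy_coupling is the correlation-scale coupling of the per-line
    aneuploidy score to the target gene's expression. response_driver
    selects the causal source of the planted drug response: the target
    gene's expression (default; partializing the target out abolishes any
    aneuploidy-response association) or the aneuploidy score itself.
    Response convention: lower = more sensitive, so planted effects enter
    with a negative sign for high-expression sensitization.
    """

    n_lines: int = 200
    n_genes: int = 2000
    n_drugs: int = 100
    target_gene: str = "GENE0000"
    target_classes: dict[str, float] = field(default_factory=lambda: {"MPS1i": 1.0})
    drugs_per_class: int = 5
    aneuploidy_coupling: float = 0.0
    noise_sd: float = 1.0
    response_driver: str = "target"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 40:
            raise ValueError("n_lines must be >= 40 for stable quartile groups")
        if self.response_driver not in ("target", "aneuploidy"):
            raise ValueError("response_driver must be 'target' or 'aneuploidy'")
        if not all(np.isfinite(v) for v in self.target_classes.values()):
            raise ValueError("effect sizes must be finite")


def simulate_panel(config: PanelSimConfig) -> tuple["PanelBundle", dict]:
    """Simulate a cell-line panel with planted gene -> drug-class structure.

    Expression is standard normal per gene; aneuploidy couples to the target
    gene's (standardized) expression with the configured strength; drugs in
    a planted class respond with -effect * driver + noise, all other
    gene-drug pairs are null. The ledger records drug classes and effects.
    """
    from .panel import PanelBundle

    rng = np.random.default_rng(config.seed)
    lines = [f"LINE{i:04d}" for i in range(config.n_lines)]
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    if config.target_gene not in genes:
        raise ValueError(f"target gene {config.target_gene!r} outside the gene universe")
    expr = pd.DataFrame(
        rng.normal(size=(config.n_genes, config.n_lines)), index=genes, columns=lines
    )
    target = expr.loc[config.target_gene].to_numpy()
    z_target = (target - target.mean()) / target.std()
    a = config.aneuploidy_coupling
    aneu_noise = rng.normal(size=config.n_lines)
    aneuploidy = a * z_target + np.sqrt(max(0.0, 1.0 - a**2)) * aneu_noise
    driver = z_target if config.response_driver == "target" else aneuploidy

    drug_rows = []
    classes: dict[str, str] = {}
    effects: dict[str, float] = {}
    d = 0
    for cls, eff in config.target_classes.items():
        for _ in range(config.drugs_per_class):
            name = f"DRUG{d:04d}"
            drug_rows.append(-eff * driver + config.noise_sd * rng.normal(size=config.n_lines))
            classes[name] = cls
            effects[name] = eff
            d += 1
    while d < config.n_drugs:
        name = f"DRUG{d:04d}"
        drug_rows.append(config.noise_sd * rng.normal(size=config.n_lines))
        classes[name] = "other"
        effects[name] = 0.0
        d += 1
    response = pd.DataFrame(drug_rows, index=list(classes), columns=lines)
    bundle = PanelBundle(
        expression=expr,
        response=response,
        aneuploidy=pd.Series(aneuploidy, index=lines, name="aneuploidy"),
        drug_class=pd.Series(classes, name="drug_class"),
    )
    ledger = {
        "target_gene": config.target_gene,
        "drug_effects": effects,
        "drug_classes": classes,
        "aneuploidy_coupling": a,
        "response_driver": config.response_driver,
        "seed": config.seed,
    }
    return bundle, ledger


# -- mitotic events ----------------------------------------------------------

# One canonical representative category per severity score.
SCORE_REPRESENTATIVE = {
    0: "correct chromosomal segregation",
    1: "dna bridge formation",
    2: "metaphase misalignment",
    3: "metaphase misalignment with micronucleus formation",
    4: "metaphase skipping",
    5: "metaphase skipping with micronucleus formation",
}


def simulate_events(
    score_dist: dict[str, dict[int, float]],
    duration_params: dict[str, tuple[float, float]],
    n_per_condition: int,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Draw mitotic events from per-condition severity distributions.

    score_dist maps condition -> {score: probability} (must sum to 1);
    duration_params maps condition -> (mean, sd) of a normal metaphase
    duration truncated at 0 minutes. Categories are the canonical
    representative for each drawn score, so re-scoring the table recovers
    the draw exactly; the ledger keeps the per-condition score histogram.
    """
    rng = np.random.default_rng(seed)
    rows = []
    hist: dict[str, dict[int, int]] = {}
    for condition in sorted(score_dist):
        probs = score_dist[condition]
        scores = sorted(probs)
        pvec = np.array([probs[s] for s in scores], dtype=float)
        if not np.isclose(pvec.sum(), 1.0):
            raise ValueError(f"score probabilities for {condition!r} must sum to 1")
        draws = rng.choice(scores, size=n_per_condition, p=pvec)
        mean, sd = duration_params.get(condition, (30.0, 10.0))
        durations = np.clip(rng.normal(mean, sd, size=n_per_condition), 0.0, None)
        hist[condition] = {int(s): int((draws == s).sum()) for s in SCORE_REPRESENTATIVE}
        for i, (s, dur) in enumerate(zip(draws, durations)):
            rows.append(
                {
                    "cell_id": f"{condition}_cell{i:04d}",
                    "condition": condition,
                    "category": SCORE_REPRESENTATIVE[int(s)],
                    "other_score": np.nan,
                    "duration_min": float(dur),
                }
            )
    events = pd.DataFrame(rows)
    ledger = {"histogram": hist, "seed": seed, "n_per_condition": n_per_condition}
    return events, ledger
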