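"""Ground-truthed synthetic data for every stage of the analysis chain.

Three generators, all deterministic given their seed:

* :func:`simulate_passages` — a batch consumer-resource model of serial
  passaging.  Within each passage the community grows to resource
  exhaustion: each resource's cell yield is divided among strains in
  proportion to ``abundance x affinity``, so a single shared resource drives
  competitive exclusion of all but the best competitor while exclusive
  resources sustain coexistence.  Transfers impose a dilution bottleneck
  with Poisson sampling (or a fixed-size founding inoculum in the in vivo
  mode), so strains near the detection limit can stochastically go extinct.
* :func:`simulate_reads` — paired-end amplicon reads from a strain mixture:
  fragment strains are multinomial in the true abundances, substitution
  errors are i.i.d. per base, and mates are taken from the fragment ends.
* :func:`simulate_metabolome` — ion-intensity tables in which
  pollen-derived ions scale linearly with the dilution fraction, designated
  ions are depleted by drawn log2 effects in designated species between two
  timepoints, and a GC-MS table carries internal standards.

The default four-strain marker panel mimics the study system: four
*Lactobacillus* strains sharing a 199-bp housekeeping-gene fragment that
differs at discriminatory SNP positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import ReadPair, reverse_complement, write_fastq_pairs
from .panel import MarkerPanel

STRAINS = ("Lapi", "Lhel", "Lmel", "Lkul")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PANEL_SEED = 19900719  # fixed: the default panel is part of the package


def default_panel(
    marker_length: int = 199,
    snp_positions: tuple[int, ...] = (24, 73, 122, 171),
) -> MarkerPanel:
    """Four-strain 199-bp marker panel with one private SNP per strain.

    Strain ``i`` carries a non-reference base at the ``i``-th discriminatory
    position, so every pair of strains differs at exactly two positions and
    a single sequencing error can never convert one valid profile into
    another.  The backbone sequence is fixed (an internal constant seed), so
    the panel is identical across runs and processes.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    backbone = rng.choice(_BASES, size=marker_length)
    seqs = []
    for i in range(len(STRAINS)):
        seq = backbone.copy()
        pos = snp_positions[i]
        # cyclic next base: guaranteed different from the backbone
        current = int(np.flatnonzero(_BASES == seq[pos])[0])
        seq[pos] = _BASES[(current + 1) % 4]
        seqs.append(seq.tobytes().decode("ascii"))
    return MarkerPanel.from_references(list(STRAINS), seqs, list(snp_positions))


# ---------------------------------------------------------------------------
# consumer-resource serial-passage model


@dataclass(frozen=True)
class ResourceModel:
    """Batch consumer-resource model for one growth cycle.

    ``supply`` is the amount of each resource provided per passage (arbitrary
    concentration units), ``preference`` the strain x resource affinity
    matrix (weights >= 0), and ``yield_per_unit`` the cells produced per unit
    of resource.  ``baseline_growth`` adds a small resource-independent cell
    yield to every strain still present (a shared-substrate floor).
    """

    supply: tuple[float, ...]
    preference: tuple[tuple[float, ...], ...]
    yield_per_unit: float = 1.0
    baseline_growth: float = 0.0

    def __post_init__(self) -> None:
        pref = np.asarray(self.preference, dtype=float)
        if pref.ndim != 2 or pref.shape[1] != len(self.supply):
            raise ValueError("preference must be strains x resources")
        if (pref < 0).any() or min(self.supply) < 0:
            raise ValueError("affinities and supplies must be >= 0")
        if not (pref.max(axis=1) > 0).all():
            raise ValueError("every strain needs at least one positive affinity")

    @property
    def n_strains(self) -> int:
        return len(self.preference)

    @property
    def n_resources(self) -> int:
        return len(self.supply)


@dataclass(frozen=True)
class PassageDesign:
    """Transfer-experiment design: bottleneck, depth, noise, and seed."""

    n_passages: int = 21
    dilution: float = 0.05  # 1:20 transfer
    inoculum_size: float = 2.5e7  # cells per strain at passage 1
    n_replicates: int = 3
    cfu_cv: float = 0.2
    depth: int = 10_000
    error_rate: float = 0.001
    read_len: int = 120
    mode: str = "invitro"  # "invitro" | "invivo"
    host_inoculum: int = 100_000  # founding cells per bee (in vivo mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dilution < 1):
            raise ValueError("dilution must be in (0, 1)")
        if self.mode not in ("invitro", "invivo"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated transfer experiment.

    ``abundances[r, p, s]`` is the end-of-passage abundance of strain ``s``
    in replicate ``r`` at passage ``p+1``.
    """

    strain_names: tuple[str, ...]
    abundances: np.ndarray  # (replicates, passages, strains)
    extinct: np.ndarray  # (replicates,) bool: community fully extinct
    model: ResourceModel | None = None
    design: PassageDesign | None = None
    totals: np.ndarray | None = None  # (replicates, passages) noisy loads
    read_truth: dict = field(default_factory=dict)  # sample_id -> {read_id: strain}
    barcode_map: dict[str, str] = field(default_factory=dict)


def grow_batch(inoculum: np.ndarray, model: ResourceModel) -> tuple[np.ndarray, np.ndarray]:
    """One batch growth cycle to resource exhaustion.

    Each resource ``r`` contributes ``supply_r * yield_per_unit`` cells,
    split among strains proportionally to ``inoculum_s * preference_sr``.
    Returns (final abundances, per-resource consumed supply); a resource
    with no consumers present is left unconsumed.
    """
    n = np.asarray(inoculum, dtype=float)
    pref = np.asarray(model.preference, dtype=float)
    supply = np.asarray(model.supply, dtype=float)
    weights = n[:, None] * pref  # (S, R)
    denom = weights.sum(axis=0)
    consumed = np.where(denom > 0, supply, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom > 0, weights / np.where(denom > 0, denom, 1.0), 0.0)
    produced = share @ (consumed * model.yield_per_unit)
    if model.baseline_growth:
        produced = produced + model.baseline_growth * (n > 0)
    return n + produced, consumed


def simulate_passages(
    model: ResourceModel, design: PassageDesign
) -> SimulationTruth:
    """Serial-passage trajectories under the consumer-resource model.

    Passage ``p`` grows the inoculum to resource exhaustion and records the
    final abundances; the next inoculum is a Poisson draw of
    ``dilution x final`` (in vitro) or a multinomial founding inoculum of
    ``host_inoculum`` cells (in vivo).  Fully extinct communities halt with
    a flag; remaining passages stay zero.
    """
    rng = np.random.default_rng(design.seed)
    S = model.n_strains
    abund = np.zeros((design.n_replicates, design.n_passages, S))
    extinct = np.zeros(design.n_replicates, dtype=bool)
    for rep in range(design.n_replicates):
        n = np.full(S, float(design.inoculum_size))
        for p in range(design.n_passages):
            if n.sum() == 0:
                extinct[rep] = True
                break
            final, _ = grow_batch(n, model)
            abund[rep, p] = final
            if design.mode == "invitro":
                n = rng.poisson(design.dilution * final).astype(float)
            else:
                total = final.sum()
                n = rng.multinomial(
                    design.host_inoculum, final / total
                ).astype(float) if total > 0 else np.zeros(S)
    names = STRAINS if S == len(STRAINS) else tuple(f"strain_{i}" for i in range(S))
    return SimulationTruth(
        strain_names=names, abundances=abund, extinct=extinct,
        model=model, design=design,
    )


def simulate_totals(
    abundances: np.ndarray, cv: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Log-normally noisy total loads around true community totals.

    The multiplicative noise has unit mean and coefficient of variation
    ``cv`` (``sigma^2 = ln(1 + cv^2)``); zero truth stays exactly zero.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = np.asarray(abundances, dtype=float).sum(axis=-1)
    if cv == 0:
        return totals
    sigma2 = np.log1p(cv**2)
    noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=totals.shape)
    return totals * noise


# ---------------------------------------------------------------------------
# amplicon read simulator


def _rows_to_strings(mat: np.ndarray) -> list[str]:
    return [row.tobytes().decode("ascii") for row in mat]


def simulate_reads(
    abundances,
    panel: MarkerPanel,
    depth: int,
    error_rate: float = 0.001,
    read_len: int = 120,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S0",
    barcode: str | None = None,
) -> tuple[list[ReadPair], dict[str, str]]:
    """Paired-end reads from a strain mixture, with per-read truth labels.

    The strain of each fragment is multinomial in the (normalised)
    abundances; substitution errors occur i.i.d. per base at ``error_rate``
    (the erroneous base is uniform over the three alternatives); per-base
    qualities are drawn uniformly from Phred 33–41, independent of the
    error process.  The forward mate is the first ``read_len`` bases of the
    fragment and the reverse mate the reverse complement of the last
    ``read_len``, so the mates overlap by ``2*read_len - marker_length``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    L = panel.marker_length
    if not (L // 2 < read_len <= L):
        raise ValueError("read_len must cover more than half the marker")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(abundances, dtype=float)
    if p.sum() <= 0:
        raise ValueError("abundances must have positive sum")
    counts = rng.multinomial(depth, p / p.sum())
    strain_of = np.repeat(np.arange(panel.n_strains), counts)
    rng.shuffle(strain_of)

    refs = np.stack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8)
         for s in panel.reference_sequences]
    )
    frags = refs[strain_of]  # (depth, L) copies
    if error_rate > 0:
        err = rng.random(frags.shape) < error_rate
        if err.any():
            # cyclic shift by 1..3 guarantees a different base
            base_idx = np.searchsorted(_BASES, frags[err])
            shift = rng.integers(1, 4, size=base_idx.shape)
            frags = frags.copy()
            frags[err] = _BASES[(base_idx + shift) % 4]

    fwd = frags[:, :read_len]
    rev_region = frags[:, L - read_len :]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    rev = comp[rev_region[:, ::-1]]
    fq = rng.integers(33, 42, size=(depth, read_len)) + 33
    rq = rng.integers(33, 42, size=(depth, read_len)) + 33

    pairs = []
    truth: dict[str, str] = {}
    fwd_s = _rows_to_strings(fwd)
    rev_s = _rows_to_strings(rev)
    fq_s = _rows_to_strings(fq.astype(np.uint8))
    rq_s = _rows_to_strings(rq.astype(np.uint8))
    for i in range(depth):
        rid = f"{sample_id}_r{i:06d}"
        pairs.append(ReadPair(rid, fwd_s[i], fq_s[i], rev_s[i], rq_s[i], barcode))
        truth[rid] = panel.strain_names[strain_of[i]]
    return pairs, truth


def make_barcodes(n: int, length: int = 8, seed: int = 7) -> list[str]:
    """Distinct random barcodes (deterministic for a given seed)."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = rng.choice(_BASES, size=length).tobytes().decode("ascii")
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


# ---------------------------------------------------------------------------
# metabolome simulator


@dataclass(frozen=True)
class ConsumptionDesign:
    """How many ions are depleted, and in how many species.

    Defaults mirror the scale of the study system: of the pollen-derived
    ions, 24 decrease in all four species, 24 in a 2–3 species subset, and
    28 in a single species, with log2 effect sizes drawn uniformly from
    ``effect_range`` (default 4- to 16-fold depletion, i.e. consumed
    substrates sit comfortably above the 2-fold flagging threshold).
    """

    n_all_species: int = 24
    n_subset: int = 24
    n_single: int = 28
    effect_range: tuple[float, float] = (2.0, 4.0)


@dataclass
class MetabolomeTruth:
    """Simulated tables plus ground-truth labels."""

    ion_table: pd.DataFrame
    dilution_table: pd.DataFrame
    gcms_table: pd.DataFrame
    is_pollen_derived: dict[str, bool]
    decreased_in: dict[str, tuple[str, ...]]
    gcms_depleted: dict[str, float]  # metabolite -> true log2 effect at final time


def simulate_metabolome(
    n_ions: int = 657,
    frac_pollen_derived: float = 406 / 657,
    design: ConsumptionDesign | None = None,
    noise_cv: float = 0.1,
    seed: int = 0,
    species: tuple[str, ...] = STRAINS,
    n_bio: int = 3,
    n_tech: int = 2,
    n_dilution_steps: int = 10,
    n_dilution_reps: int = 3,
    t0: float = 0.0,
    t_final: float = 16.0,
    n_gcms_metabolites: int = 20,
    n_gcms_depleted: int = 6,
    n_gcms_reps: int = 5,
) -> MetabolomeTruth:
    """Untargeted ion tables, a pollen dilution series, and a GC-MS table.

    Pollen-derived ions are linear in the dilution fraction (10 serial 2x
    dilutions, ``n_dilution_reps`` replicates each) and absent from water
    blanks; medium-derived ions are flat across the series and present in
    water.  Designated pollen ions drop by drawn log2 effects in designated
    species between ``t0`` and ``t_final``.  All noise is multiplicative
    log-normal with coefficient of variation ``noise_cv`` (technical
    replicates at half that).  The GC-MS table carries three internal
    standards per run and ``n_gcms_depleted`` metabolites depleted linearly
    in time (in log2 space) to a drawn effect at 24 h.
    """
    design = design or ConsumptionDesign()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    sigma_tech = np.sqrt(np.log1p((noise_cv / 2) ** 2))

    def noise(shape, s=sigma):
        return rng.lognormal(-s**2 / 2, s, size=shape)

    ions = [f"ion_{i:04d}" for i in range(n_ions)]
    base = 10 ** rng.uniform(3, 6, size=n_ions)
    n_pollen = int(round(frac_pollen_derived * n_ions))
    pollen_idx = rng.choice(n_ions, size=n_pollen, replace=False)
    is_pollen = np.zeros(n_ions, dtype=bool)
    is_pollen[pollen_idx] = True

    # --- dilution series ---------------------------------------------------
    fractions = 0.5 ** np.arange(1, n_dilution_steps + 1)
    dil_rows = []
    for i, ion in enumerate(ions):
        for frac in fractions:
            level = base[i] * frac if is_pollen[i] else base[i]
            for rep in range(n_dilution_reps):
                dil_rows.append(
                    {"ion_id": ion, "condition": "dilution", "fraction": frac,
                     "rep": rep, "intensity": level * noise(())}
                )
        for rep in range(n_dilution_reps):
            dil_rows.append(
                {"ion_id": ion, "condition": "undiluted", "fraction": np.nan,
                 "rep": rep, "intensity": base[i] * noise(())}
            )
            water_level = 0.0 if is_pollen[i] else base[i]
            dil_rows.append(
                {"ion_id": ion, "condition": "water", "fraction": np.nan,
                 "rep": rep,
                 "intensity": water_level * noise(()) if water_level else 0.0}
            )
    dilution_table = pd.DataFrame(dil_rows)

    # --- per-species consumption -------------------------------------------
    n_consumed = design.n_all_species + design.n_subset + design.n_single
    if n_consumed > n_pollen:
        raise ValueError("more consumed ions than pollen-derived ions")
    consumed_ids = rng.choice(pollen_idx, size=n_consumed, replace=False)
    decreased_in: dict[str, tuple[str, ...]] = {}
    k = 0
    for _ in range(design.n_all_species):
        decreased_in[ions[consumed_ids[k]]] = tuple(species)
        k += 1
    for _ in range(design.n_subset):
        size = int(rng.integers(2, len(species)))  # 2..n_species-1
        chosen = rng.choice(len(species), size=size, replace=False)
        decreased_in[ions[consumed_ids[k]]] = tuple(species[j] for j in sorted(chosen))
        k += 1
    for _ in range(design.n_single):
        j = int(rng.integers(len(species)))
        decreased_in[ions[consumed_ids[k]]] = (species[j],)
        k += 1

    lo, hi = design.effect_range
    effects = {
        (ion, sp): float(rng.uniform(lo, hi))
        for ion, sps in decreased_in.items()
        for sp in sps
    }

    ion_rows = []
    for sp in species:
        for i, ion in enumerate(ions):
            for tp in (t0, t_final):
                mean = base[i]
                if tp == t_final and (ion, sp) in effects:
                    mean = base[i] * 2.0 ** (-effects[(ion, sp)])
                bio_levels = mean * noise(n_bio)
                for b in range(n_bio):
                    tech = bio_levels[b] * noise(n_tech, sigma_tech)
                    for t in range(n_tech):
                        ion_rows.append(
                            {"ion_id": ion, "condition": sp, "timepoint": tp,
                             "bio_rep": b, "tech_rep": t, "intensity": tech[t]}
                        )
    ion_table = pd.DataFrame(ion_rows)

    # --- GC-MS -------------------------------------------------------------
    timepoints = (0.0, 8.0, 16.0, 24.0)
    standards = ("norleucine", "norvaline", "U13C-glucose")
    mets = [f"met_{i:02d}" for i in range(n_gcms_metabolites)]
    met_base = 10 ** rng.uniform(4, 6, size=n_gcms_metabolites)
    depleted_idx = rng.choice(n_gcms_metabolites, size=n_gcms_depleted, replace=False)
    gcms_depleted = {
        mets[j]: float(rng.uniform(2.5, 4.0)) for j in depleted_idx
    }
    gcms_rows = []
    for tp in timepoints:
        for rep in range(n_gcms_reps):
            for std in standards:
                gcms_rows.append(
                    {"metabolite": std, "timepoint": tp, "rep": rep,
                     "area": 1e6 * noise((), sigma_tech),
                     "is_internal_standard": True}
                )
            for j, met in enumerate(mets):
                mean = met_base[j]
                if met in gcms_depleted:
                    mean = met_base[j] * 2.0 ** (-gcms_depleted[met] * tp / 24.0)
                gcms_rows.append(
                    {"metabolite": met, "timepoint": tp, "rep": rep,
                     "area": mean * noise(()), "is_internal_standard": False}
                )
    gcms_table = pd.DataFrame(gcms_rows)

    return MetabolomeTruth(
        ion_table=ion_table,
        dilution_table=dilution_table,
        gcms_table=gcms_table,
        is_pollen_derived={ion: bool(is_pollen[i]) for i, ion in enumerate(ions)},
        decreased_in=decreased_in,
        gcms_depleted=gcms_depleted,
    )


# ---------------------------------------------------------------------------
# scenario presets


def exclusion_model() -> ResourceModel:
    """One shared resource (glucose-like): competitive exclusion regime.

    Affinities are spread widely enough that the three weaker competitors
    fall below a 1e5 detection bound within ~11 passages of a 1:20 transfer
    series, as in the glucose co-cultures.
    """
    return ResourceModel(
        supply=(1.0,),
        preference=((1.0,), (0.3,), (0.25,), (0.2,)),
        yield_per_unit=2e9,
    )


def partition_model() -> ResourceModel:
    """Four exclusive resources (pollen-like): stable coexistence regime."""
    capacities = (1.0e9, 7.0e8, 5.0e8, 3.0e8)
    pref = tuple(
        tuple(1.0 if r == s else 0.0 for r in range(4)) for s in range(4)
    )
    return ResourceModel(supply=capacities, preference=pref, yield_per_unit=1.0)


def invivo_model() -> ResourceModel:
    """Partitioned within-host niches at gut-scale carrying capacities."""
    capacities = (1.0e8, 3.0e7, 1.0e7, 3.0e6)
    pref = tuple(
        tuple(1.0 if r == s else 0.0 for r in range(4)) for s in range(4)
    )
    return ResourceModel(supply=capacities, preference=pref, yield_per_unit=1.0)


def scenario(name: str, seed: int = 0, **design_overrides) -> tuple[ResourceModel, PassageDesign]:
    """Preset (model, design) pairs: ``exclusion``, ``partition``, ``invivo``."""
    if name == "exclusion":
        model = exclusion_model()
        design = PassageDesign(n_passages=21, seed=seed, **design_overrides)
    elif name == "partition":
        model = partition_model()
        design = PassageDesign(n_passages=21, seed=seed, **design_overrides)
    elif name == "invivo":
        model = invivo_model()
        design = PassageDesign(
            n_passages=7, mode="invivo", inoculum_size=2.5e4,
            seed=seed, **design_overrides,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}")
    return model, design


def run_scenario(
    name: str,
    seed: int = 0,
    out_dir: str | Path | None = None,
    sequence_replicate: int = 0,
    **design_overrides,
) -> SimulationTruth:
    """Simulate a scenario end to end; optionally write FASTQ/CSV/truth files.

    Reads are generated for every passage of one replicate (each passage is
    one barcoded sample), total loads for all replicates.  When ``out_dir``
    is given, writes ``reads_R1.fastq``/``reads_R2.fastq``, ``barcodes.tsv``,
    ``totals.csv``, and ``truth.json``.
    """
    model, design = scenario(name, seed, **design_overrides)
    truth = simulate_passages(model, design)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    truth.totals = simulate_totals(truth.abundances, design.cfu_cv, rng)

    barcodes = make_barcodes(design.n_passages)
    all_pairs: list[ReadPair] = []
    barcode_map: dict[str, str] = {}
    rep = sequence_replicate
    for p in range(design.n_passages):
        sample = f"{name}_rep{rep}_P{p + 1}"
        barcode_map[barcodes[p]] = sample
        abund = truth.abundances[rep, p]
        if abund.sum() == 0:
            continue
        pairs, labels = simulate_reads(
            abund, default_panel(), design.depth, design.error_rate,
            design.read_len, rng, sample_id=sample, barcode=barcodes[p],
        )
        all_pairs.extend(pairs)
        truth.read_truth[sample] = labels

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq_pairs(all_pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
        with open(out / "barcodes.tsv", "w") as fh:
            fh.write("barcode\tsample_id\n")
            for bc, sample in barcode_map.items():
                fh.write(f"{bc}\t{sample}\n")
        totals_df = pd.DataFrame(
            [
                {"replicate": r, "passage": p + 1, "total_load": truth.totals[r, p]}
                for r in range(design.n_replicates)
                for p in range(design.n_passages)
            ]
        )
        totals_df.to_csv(out / "totals.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "scenario": name,
                    "seed": seed,
                    "strain_names": list(truth.strain_names),
                    "design": asdict(design),
                    "abundances": truth.abundances.tolist(),
                    "read_truth": truth.read_truth,
                },
                fh,
            )
    truth.barcode_map = barcode_map
    return truth
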