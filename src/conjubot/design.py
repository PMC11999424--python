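"""Experiment-design model: reagents, sources, and the mixing pattern.

An :class:`ExperimentDesign` is the declarative input to both workflow
compilers.  It lists the antibiotics, plasmids, donor *E. coli* sources
(50 mL tube cultures) and recipient *Streptomyces* spore sources (15 mL
tubes), plus — for conjugation — an ordered mixing pattern of
(E. coli, Streptomyces) pairs with per-pair replicate counts.

Designs are read from a single tab-separated table with a leading ``kind``
column (``antibiotic | plasmid | ecoli | strep | pair``); see
:func:`parse_design_table` for the schema.  A seeded fixture generator
produces random valid conjugation designs for testing and simulation.

Capacity limits reflect the single-deck conjugation setup: at most 18
E. coli tubes (three 6-position 50 mL racks), 30 Streptomyces tubes (two
15-position 15 mL racks) and 192 reactions (two 96-deep-well plates).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .errors import DesignError

__all__ = [
    "MAX_ECOLI",
    "MAX_STREP",
    "MAX_REACTIONS",
    "AntibioticSpec",
    "PlasmidSpec",
    "EcoliSource",
    "StrepSource",
    "MixPair",
    "MixPattern",
    "ExperimentDesign",
    "parse_design_table",
    "expand_pattern",
    "generate_fixture_design",
    "generate_heatshock_fixture",
    "validate_design",
]

#: Conjugation-deck capacity limits.
MAX_ECOLI = 18
MAX_STREP = 30
MAX_REACTIONS = 192

#: Target spore load per 150 uL recipient aliquot.
DEFAULT_SPORES_PER_ALIQUOT = 1e8

#: Default plasmid DNA amount per transformation, ng.
DEFAULT_DNA_NG = 50.0


@dataclass(frozen=True)
class AntibioticSpec:
    """A selection antibiotic and its final working concentration (ug/mL)."""

    name: str
    final_conc: float


@dataclass(frozen=True)
class PlasmidSpec:
    """A plasmid, the antibiotic that selects for it, and ng DNA per transformation."""

    name: str
    selection_antibiotic: str
    dna_amount: float = DEFAULT_DNA_NG


@dataclass(frozen=True)
class EcoliSource:
    """A donor (or competent-cell) *E. coli* culture in a 50 mL tube.

    ``plasmid`` names the plasmid the strain carries (conjugation) or is to
    receive (heat shock).  ``fill_uL`` is the stated liquid fill of the tube,
    used by source-volume checks when provided.
    """

    id: str
    plasmid: str
    sterile: bool = False
    tube_format: str = "50ml"
    fill_uL: float | None = None


@dataclass(frozen=True)
class StrepSource:
    """A *Streptomyces* spore suspension in a 15 mL tube (~1e8 spores / 150 uL)."""

    id: str
    spore_count: float = DEFAULT_SPORES_PER_ALIQUOT
    tube_format: str = "15ml"
    fill_uL: float | None = None


@dataclass(frozen=True)
class MixPair:
    """One distinct (E. coli, Streptomyces) combination with a replicate count."""

    ecoli_id: str
    strep_id: str
    replicates: int = 1


@dataclass(frozen=True)
class MixPattern:
    """Ordered list of distinct pairs; reactions = sum of replicates."""

    pairs: tuple[MixPair, ...] = ()

    def total_reactions(self) -> int:
        return sum(p.replicates for p in self.pairs)


@dataclass(frozen=True)
class ExperimentDesign:
    """A validated experiment design for one workflow run."""

    mode: str  # "heatshock" | "conjugation"
    antibiotics: tuple[AntibioticSpec, ...] = ()
    plasmids: tuple[PlasmidSpec, ...] = ()
    ecoli_sources: tuple[EcoliSource, ...] = ()
    strep_sources: tuple[StrepSource, ...] = ()
    mix_pattern: MixPattern = field(default_factory=MixPattern)


# ---------------------------------------------------------------------------
# validation

def validate_design(design: ExperimentDesign) -> ExperimentDesign:
    """Check invariants; raise :class:`DesignError` on the first violation.

    Checks id uniqueness, reference resolution, positivity of concentrations
    and amounts, and (for conjugation) the deck capacity limits.
    """
    if design.mode not in ("heatshock", "conjugation"):
        raise DesignError("mode", f"unknown mode {design.mode!r}")

    def _unique(label: str, names: list[str]) -> None:
        seen: set[str] = set()
        for n in names:
            if n in seen:
                raise DesignError("duplicate", f"duplicate {label} id {n!r}")
            seen.add(n)

    _unique("antibiotic", [a.name for a in design.antibiotics])
    _unique("plasmid", [p.name for p in design.plasmids])
    # E. coli and Streptomyces ids share the provenance namespace.
    _unique("source", [e.id for e in design.ecoli_sources] + [s.id for s in design.strep_sources])

    ab_names = {a.name for a in design.antibiotics}
    pl_names = {p.name for p in design.plasmids}
    ec_ids = {e.id for e in design.ecoli_sources}
    st_ids = {s.id for s in design.strep_sources}

    for a in design.antibiotics:
        if not a.final_conc > 0:
            raise DesignError("invalid", f"antibiotic {a.name!r}: final_conc must be > 0")
    for p in design.plasmids:
        if p.selection_antibiotic not in ab_names:
            raise DesignError(
                "reference", f"plasmid {p.name!r}: unknown antibiotic {p.selection_antibiotic!r}"
            )
        if not p.dna_amount > 0:
            raise DesignError("invalid", f"plasmid {p.name!r}: dna_amount must be > 0")
    for e in design.ecoli_sources:
        if e.plasmid not in pl_names:
            raise DesignError("reference", f"ecoli {e.id!r}: unknown plasmid {e.plasmid!r}")
    for pair in design.mix_pattern.pairs:
        if pair.ecoli_id not in ec_ids:
            raise DesignError("reference", f"pair: unknown ecoli id {pair.ecoli_id!r}")
        if pair.strep_id not in st_ids:
            raise DesignError("reference", f"pair: unknown strep id {pair.strep_id!r}")
        if pair.replicates < 1:
            raise DesignError("invalid", "pair replicates must be >= 1")

    if design.mode == "conjugation":
        if len(design.ecoli_sources) > MAX_ECOLI:
            raise DesignError(
                "capacity", f"{len(design.ecoli_sources)} E. coli sources > {MAX_ECOLI}"
            )
        if len(design.strep_sources) > MAX_STREP:
            raise DesignError(
                "capacity", f"{len(design.strep_sources)} Streptomyces sources > {MAX_STREP}"
            )
        total = design.mix_pattern.total_reactions()
        if total > MAX_REACTIONS:
            raise DesignError("capacity", f"{total} reactions > {MAX_REACTIONS}")
    else:
        if design.strep_sources or design.mix_pattern.pairs:
            raise DesignError("mode", "heat-shock design cannot carry Streptomyces rows or pairs")
    return design


# ---------------------------------------------------------------------------
# TSV parsing

#: Canonical column order of the design table.
TSV_COLUMNS = (
    "kind",
    "id",
    "plasmid",
    "antibiotic",
    "final_conc_ug_per_ml",
    "dna_ng",
    "spores_per_aliquot",
    "fill_uL",
    "ecoli",
    "strep",
    "replicates",
)


def _num(row: dict, col: str, lineno: int, default: float | None = None) -> float | None:
    raw = row.get(col, "").strip()
    if raw == "":
        return default
    try:
        return float(raw)
    except ValueError:
        raise DesignError("parse", f"line {lineno}: bad number {raw!r} in column {col!r}") from None


def _req(row: dict, col: str, lineno: int) -> str:
    raw = row.get(col, "").strip()
    if raw == "":
        raise DesignError("parse", f"line {lineno}: missing required column {col!r}")
    return raw


def parse_design_table(tsv_text: str) -> ExperimentDesign:
    """Parse a design table (tab-separated text) into a validated design.

    The first line is a header naming a subset of :data:`TSV_COLUMNS`
    (``kind`` is mandatory).  Each following non-blank, non-``#`` line is one
    record; the ``kind`` column selects the record type.  Order is preserved.
    Mode is inferred: a design with ``strep`` or ``pair`` rows is a
    conjugation design, otherwise heat shock.

    Raises
    ------
    DesignError
        ``parse`` (malformed row, with line number), ``duplicate``,
        ``reference`` or ``capacity`` per the validation rules.
    """
    lines = tsv_text.splitlines()
    if not lines:
        raise DesignError("parse", "empty design table")
    header = [h.strip() for h in lines[0].split("\t")]
    if "kind" not in header:
        raise DesignError("parse", "line 1: header must contain a 'kind' column")
    for h in header:
        if h not in TSV_COLUMNS:
            raise DesignError("parse", f"line 1: unknown column {h!r}")

    antibiotics: list[AntibioticSpec] = []
    plasmids: list[PlasmidSpec] = []
    ecoli: list[EcoliSource] = []
    strep: list[StrepSource] = []
    pairs: list[MixPair] = []

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) > len(header):
            raise DesignError("parse", f"line {lineno}: {len(cells)} fields for {len(header)} columns")
        row = dict(zip(header, (c.strip() for c in cells)))
        kind = _req(row, "kind", lineno)
        if kind == "antibiotic":
            conc = _num(row, "final_conc_ug_per_ml", lineno)
            if conc is None:
                raise DesignError("parse", f"line {lineno}: antibiotic needs final_conc_ug_per_ml")
            antibiotics.append(AntibioticSpec(_req(row, "id", lineno), conc))
        elif kind == "plasmid":
            plasmids.append(
                PlasmidSpec(
                    _req(row, "id", lineno),
                    _req(row, "antibiotic", lineno),
                    _num(row, "dna_ng", lineno, DEFAULT_DNA_NG),
                )
            )
        elif kind == "ecoli":
            ecoli.append(
                EcoliSource(
                    _req(row, "id", lineno),
                    _req(row, "plasmid", lineno),
                    fill_uL=_num(row, "fill_uL", lineno),
                )
            )
        elif kind == "strep":
            strep.append(
                StrepSource(
                    _req(row, "id", lineno),
                    spore_count=_num(row, "spores_per_aliquot", lineno, DEFAULT_SPORES_PER_ALIQUOT),
                    fill_uL=_num(row, "fill_uL", lineno),
                )
            )
        elif kind == "pair":
            reps = _num(row, "replicates", lineno, 1.0)
            if reps != int(reps) or int(reps) < 1:
                raise DesignError("parse", f"line {lineno}: replicates must be a positive integer")
            pairs.append(MixPair(_req(row, "ecoli", lineno), _req(row, "strep", lineno), int(reps)))
        else:
            raise DesignError("parse", f"line {lineno}: unknown kind {kind!r}")

    mode = "conjugation" if (strep or pairs) else "heatshock"
    design = ExperimentDesign(
        mode=mode,
        antibiotics=tuple(antibiotics),
        plasmids=tuple(plasmids),
        ecoli_sources=tuple(ecoli),
        strep_sources=tuple(strep),
        mix_pattern=MixPattern(tuple(pairs)),
    )
    return validate_design(design)


# ---------------------------------------------------------------------------
# pattern expansion

def expand_pattern(design: ExperimentDesign) -> list[tuple[str, str]]:
    """Flatten the mixing pattern into the ordered reaction list.

    Replicates of each distinct pair are emitted consecutively, in pattern
    order; the result drives well assignment (fill order is reaction order).
    """
    if design.mode != "conjugation":
        raise DesignError("mode", "expand_pattern requires a conjugation design")
    reactions: list[tuple[str, str]] = []
    for pair in design.mix_pattern.pairs:
        reactions.extend((pair.ecoli_id, pair.strep_id) for _ in range(pair.replicates))
    if len(reactions) > MAX_REACTIONS:
        raise DesignError("capacity", f"{len(reactions)} reactions > {MAX_REACTIONS}")
    return reactions


# ---------------------------------------------------------------------------
# fixture generation

_FIXTURE_ANTIBIOTICS = (
    AntibioticSpec("apramycin", 100.0),
    AntibioticSpec("kanamycin", 50.0),
    AntibioticSpec("chloramphenicol", 25.0),
)


def generate_fixture_design(
    seed: int, n_ecoli: int, n_strep: int, n_reactions: int
) -> ExperimentDesign:
    """Generate a deterministic, valid conjugation design for testing.

    The same ``seed`` always yields the identical design; different seeds
    shuffle the pair ordering and replicate split.  Counts outside the deck
    capacities raise ``DesignError(capacity)``.
    """
    if not (1 <= n_ecoli <= MAX_ECOLI):
        raise DesignError("capacity", f"n_ecoli={n_ecoli} outside 1..{MAX_ECOLI}")
    if not (1 <= n_strep <= MAX_STREP):
        raise DesignError("capacity", f"n_strep={n_strep} outside 1..{MAX_STREP}")
    if not (1 <= n_reactions <= MAX_REACTIONS):
        raise DesignError("capacity", f"n_reactions={n_reactions} outside 1..{MAX_REACTIONS}")

    rng = random.Random(seed)
    n_plasmids = 1 + rng.randrange(min(3, n_ecoli))
    plasmids = tuple(
        PlasmidSpec(f"pCB{i + 1:02d}", _FIXTURE_ANTIBIOTICS[i % len(_FIXTURE_ANTIBIOTICS)].name)
        for i in range(n_plasmids)
    )
    ecoli = tuple(
        EcoliSource(f"EC{i + 1:02d}", plasmids[i % n_plasmids].name) for i in range(n_ecoli)
    )
    strep = tuple(StrepSource(f"ST{j + 1:02d}") for j in range(n_strep))

    combos = [(e.id, s.id) for e in ecoli for s in strep]
    rng.shuffle(combos)
    n_pairs = rng.randint(1, min(n_reactions, len(combos)))
    counts = [1] * n_pairs
    for _ in range(n_reactions - n_pairs):
        counts[rng.randrange(n_pairs)] += 1
    pattern = MixPattern(
        tuple(MixPair(e, s, c) for (e, s), c in zip(combos[:n_pairs], counts))
    )
    design = ExperimentDesign(
        mode="conjugation",
        antibiotics=_FIXTURE_ANTIBIOTICS,
        plasmids=plasmids,
        ecoli_sources=ecoli,
        strep_sources=strep,
        mix_pattern=pattern,
    )
    return validate_design(design)


def generate_heatshock_fixture(seed: int, n_plasmids: int = 2) -> ExperimentDesign:
    """A small deterministic heat-shock design (plasmids + competent-cell lots)."""
    rng = random.Random(seed)
    n_plasmids = max(1, n_plasmids)
    plasmids = tuple(
        PlasmidSpec(
            f"pHS{i + 1:02d}",
            _FIXTURE_ANTIBIOTICS[rng.randrange(len(_FIXTURE_ANTIBIOTICS))].name,
        )
        for i in range(n_plasmids)
    )
    ecoli = tuple(
        EcoliSource(f"CC{i + 1:02d}", plasmids[i % n_plasmids].name) for i in range(n_plasmids)
    )
    design = ExperimentDesign(
        mode="heatshock",
        antibiotics=_FIXTURE_ANTIBIOTICS,
        plasmids=plasmids,
        ecoli_sources=ecoli,
    )
    return validate_design(design)


def with_fills(design: ExperimentDesign, fills: dict[str, float]) -> ExperimentDesign:
    """Return a copy of ``design`` with stated tube fills (uL) applied by source id."""
    return replace(
        design,
        ecoli_sources=tuple(
            replace(e, fill_uL=fills.get(e.id, e.fill_uL)) for e in design.ecoli_sources
        ),
        strep_sources=tuple(
            replace(s, fill_uL=fills.get(s.id, s.fill_uL)) for s in design.strep_sources
        ),
    )
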