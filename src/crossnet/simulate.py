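"""Synthetic multi-species expression studies with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-species expression compendia with co-expressed gene modules,
a shared module vocabulary across species, ortholog groups whose members
either sit in matching modules (conserved regulation), in different modules
(diverged regulation) or have no ortholog at all, duplicated paralogs with
one conserved and one diverged copy, per-module transcription factors, and
per-module GO terms.

Expression model: every module m has a latent factor z_m ~ N(0,1) drawn per
sample; a gene in module m takes value loading · z_m + N(0, noise_sd) with
loading ~ U(0.8, 1.5).  Genes outside modules follow private latent factors
of the same form, so all genes share the same marginal variance structure.

Gene IDs are namespaced ``<species>_g<k>``; a duplicated gene's conserved
paralog copy appends ``_a`` and the diverged copy ``_b``, so the planted
truth is recoverable from IDs alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AnnotationSet,
    ExpressionMatrix,
    OrthologMap,
    write_expression,
    write_go_map,
    write_ortholog_groups,
    write_tf_list,
)

__all__ = ["ScenarioSpec", "GroundTruth", "simulate_expression", "simulate_study"]

BACKGROUND_GO = "GO:0009999"


@dataclass
class ScenarioSpec:
    """Parameters of a planted multi-species co-expression scenario.

    Defaults describe the standard desk-scale study: two species, 300 genes
    and 100 samples each, four modules of 70–75 genes, ortholog classes
    split 90/5/5 between conserved, diverged and unrelated, 10% of conserved
    ortholog partners duplicated, 8% of genes flagged as TFs, and additive
    Gaussian noise with sd 0.5 on the log scale.  Module sizes and class
    fractions are set so a planted divergence is statistically detectable: a
    diverged ortholog's mapped neighbourhood overlaps its partner's by only
    ~(fraction_diverged + duplication overhead)·size/(n_modules−1) ≈ 3–4
    genes against a null expectation of n·k/N ≈ 16, putting the lower
    hypergeometric tail well below any plausible BH cutoff.
    """

    species_names: tuple[str, ...] = ("sp1", "sp2")
    n_genes: int = 300
    n_samples: int = 100
    n_modules: int = 4
    module_size_range: tuple[int, int] = (70, 75)
    fraction_conserved: float = 0.9
    fraction_diverged: float = 0.05
    fraction_unrelated: float = 0.05
    duplication_rate: float = 0.1
    tf_fraction: float = 0.08
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if len(self.species_names) < 1:
            raise ValueError("need at least one species")
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("duplicate species names")
        fracs = (
            self.fraction_conserved,
            self.fraction_diverged,
            self.fraction_unrelated,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("ortholog class fractions must be in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("ortholog class fractions must sum to 1")
        if not 0 <= self.duplication_rate <= 1:
            raise ValueError("duplication_rate must be in [0, 1]")
        if not 0 <= self.tf_fraction <= 1:
            raise ValueError("tf_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid module_size_range")
        if self.n_modules * hi > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules of up to {hi} genes exceed "
                f"{self.n_genes} genes"
            )


@dataclass
class GroundTruth:
    """Planted truth behind a simulated study.

    ``pair_class`` holds the planted class per cross-species ortholog pair
    keyed by frozenset of namespaced gene IDs; ``module_of`` maps every
    namespaced gene ID to its module (-1 for background genes); duplications
    record, per anchor gene and target species, the conserved and diverged
    copy and which copy received the higher bit-score.
    """

    pair_class: dict[frozenset[str], str] = field(default_factory=dict)
    module_of: dict[str, int] = field(default_factory=dict)
    tf_flags: dict[str, bool] = field(default_factory=dict)
    duplications: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)

    def pairs_of_class(self, cls: str) -> list[frozenset[str]]:
        return [p for p, c in self.pair_class.items() if c == cls]


# ---------------------------------------------------------------------------
# deterministic layout shared by simulate_expression and simulate_study


class _TargetRotation:
    """Round-robin choice of a non-matching module per source module.

    Diverged partners and diverged paralog copies are spread evenly over the
    other modules; clustering them in one target module would make the
    planted divergences contaminate each other's mapped neighbourhoods.
    """

    def __init__(self, n_modules: int) -> None:
        self._counters: dict[int, int] = {m: 0 for m in range(n_modules)}
        self._n = n_modules

    def next(self, free: dict[int, list[str]], source: int) -> int | None:
        others = [m for m in range(self._n) if m != source]
        for step in range(len(others)):
            m = others[(self._counters[source] + step) % len(others)]
            if free[m]:
                self._counters[source] = (
                    self._counters[source] + step + 1
                ) % len(others)
                return m
        return None


def _layout(spec: ScenarioSpec) -> dict:
    """Module sizes, per-species gene tables, ortholog classes, TFs and GO.

    Derived from a dedicated random stream so that expression generation for
    any one species never perturbs the layout (and vice versa).
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed % (2**31), 101])
    lo, hi = spec.module_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_modules)

    anchor = spec.species_names[0]
    others = spec.species_names[1:]

    # per species: gene ids g1..gN, first sum(sizes) genes tiled into modules
    genes: dict[str, list[str]] = {}
    module_of: dict[str, int] = {}
    for sp in spec.species_names:
        ids = [f"{sp}_g{k + 1}" for k in range(spec.n_genes)]
        genes[sp] = ids
        pos = 0
        for m, size in enumerate(sizes):
            for gid in ids[pos : pos + size]:
                module_of[gid] = m
            pos += size
        for gid in ids[pos:]:
            module_of[gid] = -1

    # ortholog classes for anchor module genes
    classes = ["conserved", "diverged", "unrelated"]
    probs = [spec.fraction_conserved, spec.fraction_diverged, spec.fraction_unrelated]
    n_mod_genes = int(sizes.sum())
    anchor_module_genes = genes[anchor][:n_mod_genes]
    assigned = rng.choice(classes, size=n_mod_genes, p=probs)

    pair_class: dict[frozenset[str], str] = {}
    groups: dict[str, set[tuple[str, str]]] = {}
    bitscore: dict[frozenset[str], float] = {}
    duplications: dict[tuple[str, str], dict[str, str]] = {}
    renames: dict[str, dict[str, str]] = {sp: {} for sp in spec.species_names}

    # per other species, track which module slots / background slots are free
    free_in_module: dict[str, dict[int, list[str]]] = {}
    free_background: dict[str, list[str]] = {}
    for sp in others:
        per_mod: dict[int, list[str]] = {m: [] for m in range(spec.n_modules)}
        pos = 0
        for m, size in enumerate(sizes):
            per_mod[m] = list(genes[sp][pos : pos + size])
            pos += size
        free_in_module[sp] = per_mod
        free_background[sp] = list(genes[sp][pos:])

    rotations = {sp: _TargetRotation(spec.n_modules) for sp in others}
    group_counter = 0
    for gid, cls in zip(anchor_module_genes, assigned):
        if cls == "unrelated":
            continue
        m = module_of[gid]
        members: set[tuple[str, str]] = {(anchor, gid)}
        duplicated = cls == "conserved" and rng.random() < spec.duplication_rate
        for sp in others:
            if cls == "conserved":
                pool = free_in_module[sp][m]
                if not pool:
                    continue
                partner = pool.pop(0)
                if duplicated:
                    # conserved copy stays in the matching module; the
                    # diverged copy takes a slot in the next round-robin
                    # target module
                    mm = rotations[sp].next(free_in_module[sp], m)
                    if mm is not None:
                        div_slot = free_in_module[sp][mm].pop(0)
                        cons_id = partner + "_a"
                        div_id = div_slot + "_b"
                        renames[sp][partner] = cons_id
                        renames[sp][div_slot] = div_id
                        members.add((sp, cons_id))
                        members.add((sp, div_id))
                        pair_class[frozenset((gid, cons_id))] = "conserved"
                        pair_class[frozenset((gid, div_id))] = "diverged"
                        # bit-scores: with prob 0.5 the diverged copy scores higher
                        s_hi = 200.0 + abs(rng.normal(0, 10)) + 5.0
                        s_lo = 200.0 - abs(rng.normal(0, 10)) - 5.0
                        if rng.random() < 0.5:
                            bitscore[frozenset((gid, div_id))] = s_hi
                            bitscore[frozenset((gid, cons_id))] = s_lo
                            higher = "diverged"
                        else:
                            bitscore[frozenset((gid, cons_id))] = s_hi
                            bitscore[frozenset((gid, div_id))] = s_lo
                            higher = "conserved"
                        duplications[(gid, sp)] = {
                            "conserved_copy": cons_id,
                            "diverged_copy": div_id,
                            "higher_bitscore_copy": higher,
                        }
                        continue
                members.add((sp, partner))
                pair_class[frozenset((gid, partner))] = "conserved"
                bitscore[frozenset((gid, partner))] = 200.0 + rng.normal(0, 10)
            else:  # diverged: partner drawn from a different module
                mm = rotations[sp].next(free_in_module[sp], m)
                if mm is None:
                    continue
                partner = free_in_module[sp][mm].pop(0)
                members.add((sp, partner))
                pair_class[frozenset((gid, partner))] = "diverged"
                bitscore[frozenset((gid, partner))] = 200.0 + rng.normal(0, 10)
        if len(members) > 1:
            group_counter += 1
            groups[f"G{group_counter}"] = members

    # apply duplication renames to gene tables and module map
    for sp in spec.species_names:
        if renames[sp]:
            genes[sp] = [renames[sp].get(g, g) for g in genes[sp]]
            for old, new in renames[sp].items():
                module_of[new] = module_of.pop(old)

    # TFs: one designated regulator per module plus random extras
    tf_ids: dict[str, set[str]] = {}
    for sp in spec.species_names:
        per_mod: dict[int, list[str]] = {}
        for gid in genes[sp]:
            per_mod.setdefault(module_of[gid], []).append(gid)
        tfs = {members[0] for m, members in per_mod.items() if m >= 0}
        target = int(round(spec.tf_fraction * len(genes[sp])))
        extras = [g for g in genes[sp] if g not in tfs]
        n_extra = max(0, target - len(tfs))
        if n_extra:
            tfs.update(rng.choice(extras, size=min(n_extra, len(extras)), replace=False))
        tf_ids[sp] = tfs

    # GO: one term per module, shared across species, plus a background term
    go_maps: dict[str, dict[str, set[str]]] = {}
    for sp in spec.species_names:
        gm: dict[str, set[str]] = {}
        for gid in genes[sp]:
            terms = {BACKGROUND_GO}
            if module_of[gid] >= 0:
                terms.add(f"GO:{module_of[gid] + 1:07d}")
            gm[gid] = terms
        go_maps[sp] = gm

    truth = GroundTruth(
        pair_class=pair_class,
        module_of=dict(module_of),
        tf_flags={g: (g in tf_ids[sp]) for sp in spec.species_names for g in genes[sp]},
        duplications=duplications,
    )
    return {
        "sizes": sizes,
        "genes": genes,
        "module_of": module_of,
        "omap": OrthologMap(groups=groups, bitscore=bitscore),
        "tf_ids": tf_ids,
        "go_maps": go_maps,
        "truth": truth,
    }


def simulate_expression(spec: ScenarioSpec, species: str) -> ExpressionMatrix:
    """Generate the genes × samples expression matrix for one species.

    Deterministic given (spec.seed, species); module membership follows the
    shared layout, so matching modules across species load on independent
    per-species factors but identical gene↔module structure.
    """
    if species not in spec.species_names:
        raise ValueError(f"unknown species {species!r}")
    layout = _layout(spec)
    return _expression_for(spec, species, layout)


def _expression_for(spec: ScenarioSpec, species: str, layout: dict) -> ExpressionMatrix:
    sp_idx = spec.species_names.index(species)
    rng = np.random.default_rng([spec.seed % (2**31), 202, sp_idx])
    ids = layout["genes"][species]
    module_of = layout["module_of"]
    n, s = len(ids), spec.n_samples
    factors = rng.normal(size=(spec.n_modules, s))
    # loading floor 0.8 keeps the weakest module gene at SNR ≈ 2.6 under the
    # default noise_sd, so every planted neighbourhood is recoverable
    loadings = rng.uniform(0.8, 1.5, size=n)
    values = np.empty((n, s))
    for i, gid in enumerate(ids):
        m = module_of[gid]
        z = factors[m] if m >= 0 else rng.normal(size=s)
        values[i] = loadings[i] * z
    values += rng.normal(0.0, spec.noise_sd, size=(n, s)) if spec.noise_sd > 0 else 0.0
    samples = [f"{species}_s{j + 1}" for j in range(s)]
    return ExpressionMatrix(ids, samples, values, species=species)


def simulate_study(
    spec: ScenarioSpec,
) -> tuple[dict[str, ExpressionMatrix], OrthologMap, dict[str, AnnotationSet], GroundTruth]:
    """Generate the full multi-species study.

    Returns per-species expression matrices, the ortholog map (with planted
    conserved / diverged / unrelated classes and bit-scores), per-species
    annotation sets (TF lists and GO maps), and the ground truth.
    """
    if len(spec.species_names) < 2:
        raise ValueError("a study needs at least two species")
    layout = _layout(spec)
    matrices = {
        sp: _expression_for(spec, sp, layout) for sp in spec.species_names
    }
    annotations = {
        sp: AnnotationSet(tf_ids=layout["tf_ids"][sp], go_map=layout["go_maps"][sp])
        for sp in spec.species_names
    }
    return matrices, layout["omap"], annotations, layout["truth"]


def write_study(spec: ScenarioSpec, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a study and write every artefact in the data_io dialects.

    Writes, per species: ``<sp>_expression.tsv``, ``<sp>_tfs.txt``,
    ``<sp>_go.tsv``; plus ``groups.txt``, ``bitscores.tsv`` and
    ``ground_truth.tsv``.  Returns the mapping of artefact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, omap, annotations, truth = simulate_study(spec)
    paths: dict[str, Path] = {}
    for sp, mat in matrices.items():
        paths[f"{sp}_expression"] = out / f"{sp}_expression.tsv"
        write_expression(mat, paths[f"{sp}_expression"])
        paths[f"{sp}_tfs"] = out / f"{sp}_tfs.txt"
        write_tf_list(annotations[sp].tf_ids, paths[f"{sp}_tfs"])
        paths[f"{sp}_go"] = out / f"{sp}_go.tsv"
        write_go_map(annotations[sp].go_map, paths[f"{sp}_go"])
    paths["groups"] = out / "groups.txt"
    paths["bitscores"] = out / "bitscores.tsv"
    write_ortholog_groups(omap, paths["groups"], paths["bitscores"])
    paths["ground_truth"] = out / "ground_truth.tsv"
    with open(paths["ground_truth"], "w") as fh:
        fh.write("gene_a\tgene_b\tclass\n")
        for pair in sorted(truth.pair_class, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{truth.pair_class[pair]}\n")
    return paths
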