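"""End-to-end pipeline runner: configuration, seeding, manifest.

A single ``RunConfig`` (round-trippable through JSON) drives the full
synthetic study: pool generation, product simulation, read preprocessing,
nucleotide/structure profiling, junction fingerprinting, motif scanning,
combinatorics and the recombination ΔD grid.  One master seed spawns
independent per-stage seeds through ``numpy.random.SeedSequence``, so
re-running an identical config reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .folding import nussinov_fold, structure_profile, compare_structure_profiles
from .io_formats import collapse, quality_filter, split_by_length, write_fastq
from .motif_scan import default_catalogue, match_submotifs, motif_ligation_profile
from .pool_analysis import (
    frequency_profile,
    generate_matched_pool,
    junction_fingerprint,
    pool_combinatorics,
    rgb_signature,
)
from .recombination_sim import delta_D_grid
from .synthetic_data import (
    ErrorProfile,
    PoolSpec,
    ProductSpec,
    attach_quality,
    make_pool,
    make_products,
    write_truth_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

# stable stage order; each stage gets its own child seed of the master seed
STAGES = (
    "makepool",
    "makeproducts",
    "preprocess",
    "signature",
    "fingerprint",
    "matchedpool",
    "structureprofile",
    "motifs",
    "combinatorics",
    "simulate",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters of a full synthetic-study run."""

    seed: int = 0
    out_dir: str = "poolforge_out"
    # pool / product generation
    pool_length: int = 20
    alphabet: str = "ACGU"
    n_unique: int = 200
    redundancy: int = 10
    n_products: int = 2000
    junction_bias: dict = field(default_factory=lambda: {"CN": 8.0})
    truncation_geometric_p: float = 0.8
    # preprocessing
    min_q: int = 20
    min_fraction: float = 0.9
    error_sub_rate: float = 0.005
    error_tail_frac: float = 0.1
    # matched pools / structure
    matched_pool_n: int = 2000
    matched_pool_replicates: int = 3
    fold_sample: int = 300
    # simulation grid
    grid_rates: tuple = (0.2, 0.5, 1.0)
    grid_replicates: int = 3
    sim_n_unique: int = 100
    sim_redundancy: int = 10

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls(**data)
        if isinstance(cfg.grid_rates, list):
            cfg.grid_rates = tuple(cfg.grid_rates)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(path: Path, header: str, rows) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages on a self-generated synthetic dataset; returns the out dir.

    Any stage failure is re-raised as ``PipelineError`` naming the stage.  The
    manifest records the package version, seed, config and a checksum of every
    output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: child for name, child in zip(STAGES, ss.spawn(len(STAGES)))}

    def seed_int(stage: str) -> int:
        return int(stage_seeds[stage].generate_state(1)[0] % (2**31))

    outputs: list[Path] = []
    stage = "makepool"
    try:
        bait_spec = PoolSpec(
            length=config.pool_length,
            alphabet=config.alphabet,
            n_unique=config.n_unique,
            redundancy=config.redundancy,
        )
        bait = make_pool(bait_spec, seed=seed_int("makepool"))
        prey = make_pool(bait_spec, seed=seed_int("makepool") + 1)

        stage = "makeproducts"
        pspec = ProductSpec(
            junction_bias=dict(config.junction_bias),
            truncation_dist=("geometric", config.truncation_geometric_p),
            n_products=config.n_products,
        )
        products = make_products(bait, prey, pspec, seed=seed_int("makeproducts"))
        reads, truth = attach_quality(
            products,
            ErrorProfile(
                sub_rate=config.error_sub_rate,
                tail_frac=config.error_tail_frac,
                tail_len=max(2, config.pool_length // 4),
            ),
            seed=seed_int("makeproducts") + 1,
        )
        write_fastq(reads, out / "products.fastq")
        write_truth_table(truth, out / "truth.tsv")
        outputs += [out / "products.fastq", out / "truth.tsv"]

        stage = "preprocess"
        kept = list(quality_filter(reads, min_q=config.min_q, min_fraction=config.min_fraction))
        collapsed = collapse(kept)
        buckets, hist = split_by_length(collapsed)
        _write_tsv(
            out / "length_histogram.tsv",
            "# product size distribution (molecules per length, nt)\nlength\tcount\n",
            sorted(hist.items()),
        )
        outputs.append(out / "length_histogram.tsv")

        stage = "signature"
        full_len = 2 * config.pool_length
        full_products = [p.seq for p in products if len(p.seq) == full_len]
        profile = frequency_profile(full_products)
        profile.to_tsv(out / "frequency_profile.tsv")
        rgb = rgb_signature(profile)
        _write_tsv(
            out / "rgb_signature.tsv",
            "# RGB signature per position (0-255, real-valued)\nposition\tR\tG\tB\n",
            [(i + 1, f"{r:.2f}", f"{g:.2f}", f"{b:.2f}") for i, (r, g, b) in enumerate(rgb)],
        )
        outputs += [out / "frequency_profile.tsv", out / "rgb_signature.tsv"]

        stage = "fingerprint"
        bg = frequency_profile([s for s in _expand_background(bait, prey, full_len)])
        fp = junction_fingerprint(full_products, junction_index=config.pool_length, background=bg)
        fp.to_tsv(out / "junction_fingerprint.tsv")
        outputs.append(out / "junction_fingerprint.tsv")

        stage = "matchedpool"
        matched_reps = [
            generate_matched_pool(profile, config.matched_pool_n, seed=seed_int("matchedpool") + r)
            for r in range(config.matched_pool_replicates)
        ]

        stage = "structureprofile"
        n_fold = min(config.fold_sample, len(full_products))
        exp_structs = [nussinov_fold(s) for s in full_products[:n_fold]]
        exp_profile = structure_profile(exp_structs)
        exp_profile.to_tsv(out / "structure_profile.tsv")
        syn_profiles = [
            structure_profile([nussinov_fold(s) for s in rep[:n_fold]])
            for rep in matched_reps
        ]
        comparison = compare_structure_profiles(exp_profile, syn_profiles)
        comparison.to_tsv(out / "structure_comparison.tsv")
        outputs += [out / "structure_profile.tsv", out / "structure_comparison.tsv"]

        stage = "motifs"
        catalogue = default_catalogue()
        all_matches = []
        for p, st in zip(products[:n_fold], exp_structs):
            all_matches.extend(
                match_submotifs(st, junction_index=p.junction, catalogue=catalogue)
            )
        if all_matches:
            profiles = motif_ligation_profile(all_matches)
            _write_tsv(
                out / "motif_ligation_profiles.tsv",
                "# normalized ligation-site frequency per intra-motif bond\n"
                "motif\tbond\tfrequency\tn_matches\tflagged_fold\n",
                [
                    (mid, k, f"{mp.frequencies[k]:.6f}", mp.n_matches,
                     f"{mp.flagged.get(k, 0):.3f}" if k in mp.flagged else "")
                    for mid, mp in sorted(profiles.items())
                    for k in range(len(mp.frequencies))
                ],
            )
            outputs.append(out / "motif_ligation_profiles.tsv")

        stage = "combinatorics"
        combo = pool_combinatorics(10**15, length=config.pool_length,
                                   alphabet_size=len(config.alphabet))
        _write_tsv(
            out / "combinatorics.tsv",
            "# pool combinatorics (counts; amount in nmol)\nquantity\tvalue\n",
            sorted(combo.items()),
        )
        outputs.append(out / "combinatorics.tsv")

        stage = "simulate"
        sim_spec = PoolSpec(
            length=config.pool_length,
            alphabet=config.alphabet,
            n_unique=config.sim_n_unique,
            redundancy=config.sim_redundancy,
        )
        mean, sd = delta_D_grid(
            sim_spec,
            hydrolysis_rates=list(config.grid_rates),
            ligation_rates=list(config.grid_rates),
            replicates=config.grid_replicates,
            seed=seed_int("simulate"),
        )
        _write_tsv(
            out / "delta_D_grid.tsv",
            "# mean delta Shannon index (bits) per (hydrolysis, ligation) rate cell\n"
            "hydrolysis_rate\tligation_rate\tmean_delta_D\tsd\n",
            [
                (h, l, f"{mean[i, j]:.6f}", f"{sd[i, j]:.6f}")
                for i, h in enumerate(config.grid_rates)
                for j, l in enumerate(config.grid_rates)
            ],
        )
        outputs.append(out / "delta_D_grid.tsv")
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    config.to_json(out / "config.json")
    manifest = {
        "poolforge_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _expand_background(bait, prey, full_len: int):
    """Unligated-input background: untruncated bait+prey concatenation space."""
    bait_seqs = list(bait.entries)
    prey_seqs = list(prey.entries)
    n = min(len(bait_seqs), len(prey_seqs), 500)
    for i in range(n):
        s = bait_seqs[i] + prey_seqs[i]
        if len(s) == full_len:
            yield s
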