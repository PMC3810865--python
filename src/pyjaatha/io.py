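"""File input/output: alignments, ms-dialect haplotype text, JSFS matrices,
run configuration, and the seeded fixture generator."""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .engine import LocusConfig, add_ism_mutations, simulate_genealogies
from .finite_sites import Alignment, FiniteSitesConfig, evolve_alignment
from .models import ModelSpec, build_named_model
from .search import SearchSettings

__all__ = [
    "RunConfig",
    "load_config",
    "read_alignments",
    "write_alignment_fasta",
    "write_ms_text",
    "read_ms_text",
    "write_jsfs_text",
    "read_jsfs_text",
    "jsfs_to_table",
    "generate_fixture",
]


# ---------------------------------------------------------------------------
# alignments

def read_alignments(paths, population_map: dict[str, str]) -> list[Alignment]:
    """Read per-locus FASTA alignments.

    ``population_map`` assigns each record id to "P1", "P2" or "outgroup".
    Rows are reordered to P1, P2, outgroup; bases are uppercased.  A record
    missing from the map or a within-locus length mismatch is an error.
    """
    alignments = []
    for path in paths:
        groups: dict[str, list] = {"P1": [], "P2": [], "outgroup": []}
        length = None
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in population_map:
                raise ValueError(f"record {rec.id!r} in {path} is not in the population map")
            pop = population_map[rec.id]
            if pop not in groups:
                raise ValueError(f"record {rec.id!r} mapped to unknown group {pop!r}")
            seq = str(rec.seq).upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"record {rec.id!r} in {path} has length {len(seq)}, expected {length}")
            groups[pop].append((rec.id, seq))
        if len(groups["outgroup"]) != 1:
            raise ValueError(f"{path}: expected exactly one outgroup record, "
                             f"got {len(groups['outgroup'])}")
        ordered = groups["P1"] + groups["P2"] + groups["outgroup"]
        seqs = np.array([list(s) for _, s in ordered], dtype="U1")
        alignments.append(Alignment(
            seqs=seqs, y1=len(groups["P1"]), y2=len(groups["P2"]),
            has_outgroup=True, ids=[i for i, _ in ordered]))
    return alignments


def write_alignment_fasta(aln: Alignment, path) -> None:
    records = [SeqRecord(Seq("".join(row)), id=name, description="")
               for name, row in zip(aln.ids, aln.seqs.astype("U1"))]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# ms-dialect haplotype text (segsites / positions / 0-1 rows)

def write_ms_text(loci: list[tuple[np.ndarray, np.ndarray]], path) -> None:
    """Write loci as ms-dialect text.  Each locus is ``(positions,
    haplotypes)`` with fractional 0-based positions and a (samples, sites)
    0/1 matrix."""
    with open(path, "w") as fh:
        fh.write("ms-dialect haplotypes\n\n")
        for positions, haps in loci:
            fh.write("//\n")
            fh.write(f"segsites: {len(positions)}\n")
            if len(positions):
                fh.write("positions: " + " ".join(f"{p:.5f}" for p in positions) + "\n")
                for row in haps:
                    fh.write("".join(str(int(x)) for x in row) + "\n")
            fh.write("\n")


def read_ms_text(path) -> list[tuple[np.ndarray, np.ndarray]]:
    loci = []
    positions, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "//":
                if positions is not None:
                    loci.append((positions, np.array(rows, dtype=np.int8)))
                positions, rows = np.array([]), []
            elif line.startswith("segsites:"):
                if int(line.split()[1]) == 0:
                    positions = np.array([])
            elif line.startswith("positions:"):
                positions = np.array([float(x) for x in line.split()[1:]])
            elif line and set(line) <= {"0", "1"}:
                rows.append([int(c) for c in line])
    if positions is not None:
        loci.append((positions, np.array(rows, dtype=np.int8)
                     if rows else np.zeros((0, 0), dtype=np.int8)))
    return loci


def ts_to_ms_locus(mts) -> tuple[np.ndarray, np.ndarray]:
    """Positions (fractional, 0-based) and 0/1 haplotype matrix of a mutated
    tree sequence."""
    if mts.num_sites == 0:
        return np.array([]), np.zeros((mts.num_samples, 0), dtype=np.int8)
    positions = mts.tables.sites.position / mts.sequence_length
    G = mts.genotype_matrix()
    return positions, (G.T > 0).astype(np.int8)


# ---------------------------------------------------------------------------
# JSFS text

def write_jsfs_text(jsfs: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(jsfs, dtype=np.int64), fmt="%d")


def read_jsfs_text(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64, ndmin=2)


def jsfs_to_table(jsfs: np.ndarray) -> list[tuple[int, int, int]]:
    """Three-column (a, b, count) representation of the non-zero cells."""
    jsfs = np.asarray(jsfs)
    a, b = np.nonzero(jsfs)
    return [(int(i), int(j), int(jsfs[i, j])) for i, j in zip(a, b)]


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """A single document describing an estimation run."""

    model: ModelSpec
    locus_config: LocusConfig
    settings: SearchSettings = field(default_factory=SearchSettings)
    fsm_config: FiniteSitesConfig | None = None
    seed: int = 17
    input_paths: list[str] = field(default_factory=list)
    population_map: dict[str, str] = field(default_factory=dict)
    output_dir: str = "."

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        model_entry = d["model"]
        if isinstance(model_entry, str):
            model = build_named_model(
                model_entry, ranges={k: tuple(v) for k, v in d.get("ranges", {}).items()},
                with_alpha=bool(d.get("with_alpha", False)))
        else:
            model = ModelSpec.from_json(json.dumps(model_entry))
        locus = LocusConfig(**d["locus_config"])
        settings = SearchSettings(**d.get("settings", {}))
        fsm = d.get("fsm_config")
        fsm_config = FiniteSitesConfig(**{
            **fsm, "base_freqs": tuple(fsm.get("base_freqs", (0.25,) * 4))
        }) if fsm is not None else None
        return cls(model=model, locus_config=locus, settings=settings,
                   fsm_config=fsm_config, seed=int(d.get("seed", 17)),
                   input_paths=list(d.get("input_paths", [])),
                   population_map=dict(d.get("population_map", {})),
                   output_dir=d.get("output_dir", "."))

    def provenance(self) -> dict:
        return {
            "model": json.loads(self.model.to_json()),
            "locus_config": dataclasses.asdict(self.locus_config),
            "settings": dataclasses.asdict(self.settings),
            "fsm_config": dataclasses.asdict(self.fsm_config) if self.fsm_config else None,
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    """Load a JSON or YAML run configuration."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# fixture generator

def generate_fixture(model: ModelSpec, point: np.ndarray,
                     locus_config: LocusConfig, seed: int, out_dir,
                     fsm_config: FiniteSitesConfig | None = None) -> dict:
    """Write a complete synthetic dataset plus a truth record.

    FSM mode writes one FASTA alignment per locus; infinite-sites mode
    writes ms-dialect haplotype text.  A ``truth.json`` records the
    generating model, parameters and seed.  Byte-identical for equal seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    params = model.to_demography_params(point)
    values = model.resolve(point)
    files = []
    if fsm_config is not None:
        lc = locus_config if locus_config.has_outgroup else LocusConfig(
            n_loc=locus_config.n_loc, y1=locus_config.y1, y2=locus_config.y2,
            seq_length_bp=locus_config.seq_length_bp, rho=locus_config.rho,
            outgroup_factor=fsm_config.outgroup_factor)
        cfg = fsm_config
        if "alpha" in values:
            cfg = FiniteSitesConfig(base_freqs=cfg.base_freqs, titv=cfg.titv,
                                    alpha=values["alpha"],
                                    outgroup_factor=cfg.outgroup_factor)
        for i, ts in enumerate(simulate_genealogies(params, lc, rng)):
            aln = evolve_alignment(ts, cfg, params.theta, rng, y1=lc.y1, y2=lc.y2)
            path = out / f"locus_{i:03d}.fasta"
            write_alignment_fasta(aln, path)
            files.append(path.name)
    else:
        loci = []
        for ts in simulate_genealogies(params, locus_config, rng):
            mts = add_ism_mutations(ts, params.theta, rng)
            loci.append(ts_to_ms_locus(mts))
        path = out / "haplotypes.ms.txt"
        write_ms_text(loci, path)
        files.append(path.name)
    truth = {
        "model": json.loads(model.to_json()),
        "point_log": [float(x) for x in np.asarray(point)],
        "params": {k: (None if v is None or (isinstance(v, float) and math.isnan(v)) else v)
                   for k, v in values.items()},
        "locus_config": dataclasses.asdict(locus_config),
        "fsm_config": dataclasses.asdict(fsm_config) if fsm_config else None,
        "seed": seed,
        "files": files,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
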