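"""Delimited-text formats for maps, genotype probabilities and phenotypes.

All files are UTF-8 comma- or tab-delimited with a header row:

* map: ``linkage_group, position_cM[, marker_id]`` with positions
  non-decreasing within a group;
* genotype probabilities (long format): ``individual_id, linkage_group,
  position_cM, state_index, probability`` — absent (individual,
  position, state) triples mean probability zero; states use the
  package's lexicographic index (see :mod:`polyqtl.statespace`);
* phenotypes: ``individual_id`` plus one numeric column per trait.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import GeneticMap, KinshipGrid
from .simulate import SimPopulation, SimTruth, z_from_states
from .statespace import GenotypeStateSpace, build_state_space

__all__ = [
    "read_map",
    "read_probabilities",
    "read_phenotypes",
    "read_inputs",
    "write_simulation",
    "ParseError",
]

log = logging.getLogger("polyqtl")


class ParseError(ValueError):
    """A file violated the expected schema."""


def _read_delimited(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    # round_trip parsing keeps serialized floats bit-exact
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def read_map(path) -> GeneticMap:
    df = _read_delimited(path)
    _require(df, ["linkage_group", "position_cM"], path)
    try:
        return GeneticMap(lg=df["linkage_group"].to_numpy(dtype=int),
                          pos=df["position_cM"].to_numpy(dtype=float))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_probabilities(path, genetic_map: GeneticMap,
                       space: GenotypeStateSpace) -> KinshipGrid:
    """Long-format genotype probabilities into a kinship grid."""
    df = _read_delimited(path)
    _require(df, ["individual_id", "linkage_group", "position_cM",
                  "state_index", "probability"], path)
    individuals = list(pd.unique(df["individual_id"]))
    ind_idx = {v: i for i, v in enumerate(individuals)}
    n, p = len(individuals), space.n_states
    if df["state_index"].max() >= p or df["state_index"].min() < 0:
        raise ParseError(f"{path}: state_index outside 0..{p - 1}")

    Z_list = [np.zeros((n, p)) for _ in range(genetic_map.n_positions)]
    pos_of = {}
    for q in range(genetic_map.n_positions):
        pos_of[(int(genetic_map.lg[q]), round(float(genetic_map.pos[q]), 6))] = q
    for lg, pos, ind, st, pr in zip(
            df["linkage_group"], df["position_cM"], df["individual_id"],
            df["state_index"], df["probability"]):
        key = (int(lg), round(float(pos), 6))
        if key not in pos_of:
            raise ParseError(f"{path}: position LG {lg} @ {pos} cM is not on the map")
        Z_list[pos_of[key]][ind_idx[ind], int(st)] = float(pr)
    try:
        return KinshipGrid.from_probabilities(genetic_map, space, Z_list,
                                              individuals=individuals)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_delimited(path)
    _require(df, ["individual_id"], path)
    if df["individual_id"].duplicated().any():
        dups = df.loc[df["individual_id"].duplicated(), "individual_id"].tolist()
        raise ParseError(f"{path}: duplicated individual_id {dups}")
    return df.set_index("individual_id")


def read_inputs(map_path, probs_path, pheno_path,
                ploidy: int) -> tuple[KinshipGrid, pd.DataFrame]:
    """Read and join the three inputs on individual_id.

    Individuals present on only one side are dropped with a logged
    count; zero overlap is fatal.
    """
    gmap = read_map(map_path)
    space = build_state_space(ploidy)
    grid = read_probabilities(probs_path, gmap, space)
    pheno = read_phenotypes(pheno_path)

    genotyped = list(grid.individuals)
    shared = [i for i in genotyped if i in pheno.index]
    dropped = (len(genotyped) - len(shared)) + (len(pheno.index) - len(shared))
    if not shared:
        raise ParseError("no individuals shared between probabilities and phenotypes")
    if dropped:
        log.info("dropped %d unmatched individuals; %d analyzed", dropped, len(shared))
    keep = [genotyped.index(i) for i in shared]
    grid = KinshipGrid(grid.map, grid.space, grid.X[:, keep, :],
                       individuals=shared)
    return grid, pheno.loc[shared]


def write_simulation(out_dir, pop: SimPopulation,
                     traits: dict[str, SimTruth]) -> dict[str, Path]:
    """Write a simulated population in the package's text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gmap, space = pop.grid.map, pop.space
    paths = {}

    map_df = pd.DataFrame({"linkage_group": gmap.lg, "position_cM": gmap.pos})
    paths["map"] = out / "map.csv"
    map_df.to_csv(paths["map"], index=False)

    rows = {"individual_id": [], "linkage_group": [], "position_cM": [],
            "state_index": [], "probability": []}
    for q in range(gmap.n_positions):
        for i, ind in enumerate(pop.grid.individuals):
            rows["individual_id"].append(ind)
            rows["linkage_group"].append(int(gmap.lg[q]))
            rows["position_cM"].append(float(gmap.pos[q]))
            rows["state_index"].append(int(pop.states[i, q]))
            rows["probability"].append(1.0)
    paths["probabilities"] = out / "probabilities.csv"
    pd.DataFrame(rows).to_csv(paths["probabilities"], index=False)

    pheno = pd.DataFrame({"individual_id": pop.grid.individuals})
    for name, truth in traits.items():
        pheno[name] = truth.y
    paths["phenotypes"] = out / "phenotypes.csv"
    pheno.to_csv(paths["phenotypes"], index=False, float_format="%.17g")
    return paths


def one_hot_Z(pop: SimPopulation, q: int) -> np.ndarray:
    """Dense one-hot probability matrix of a simulated population at position q."""
    return z_from_states(pop.states[:, q], pop.space)
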