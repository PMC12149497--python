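"""Multi-generation pedigree simulation.

Generates discrete, non-overlapping generations: founders in generation 0,
then a fixed number of offspring per generation whose parents are drawn from
the previous generation. Sexes are assigned in a balanced alternating way so
random mating always finds a sire and a dam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PedigreeSpec", "simulate_pedigree"]


@dataclass
class PedigreeSpec:
    """Configuration for pedigree simulation.

    Attributes
    ----------
    n_founders
        Animals in generation 0 (unknown parents).
    n_generations
        Number of descendant generations (labels 1..n_generations).
    n_per_generation
        Offspring born in each descendant generation.
    mating_scheme
        ``random``: every offspring gets an independently drawn sire and dam.
        ``hierarchical``: a quarter of the previous generation's males serve
        as sires, each mated to a block of dams (paternal half-sib families).
    offspring_per_mating
        Under ``hierarchical``, full sibs produced per sire-dam pair.
    """

    n_founders: int
    n_generations: int = 5
    n_per_generation: int = 100
    mating_scheme: str = "random"
    offspring_per_mating: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders (one of each sex)")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.mating_scheme not in {"random", "hierarchical"}:
            raise ValueError(f"unknown mating scheme {self.mating_scheme!r}")
        if self.offspring_per_mating < 1:
            raise ValueError("offspring_per_mating must be >= 1")


def simulate_pedigree(spec: PedigreeSpec) -> pd.DataFrame:
    """Simulate a pedigree table.

    Returns a frame with columns ``animal`` (1-based id), ``sire``, ``dam``
    (0 = unknown), ``sex`` ('M'/'F') and ``generation``; parents always
    precede offspring, so the table is topologically ordered.
    """
    rng = np.random.default_rng(spec.seed)
    animal: list[int] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    gen: list[int] = []

    def add(s: int, d: int, g: int) -> int:
        i = len(animal) + 1
        animal.append(i)
        sire.append(s)
        dam.append(d)
        sex.append("M" if (i % 2 == 0) else "F")
        gen.append(g)
        return i

    for _ in range(spec.n_founders):
        add(0, 0, 0)

    prev = list(range(1, spec.n_founders + 1))
    for g in range(1, spec.n_generations + 1):
        males = [i for i in prev if sex[i - 1] == "M"]
        females = [i for i in prev if sex[i - 1] == "F"]
        if not males or not females:
            raise ValueError("previous generation lacks one sex entirely")
        newborn: list[int] = []
        if spec.mating_scheme == "random":
            ss = rng.choice(males, size=spec.n_per_generation)
            dd = rng.choice(females, size=spec.n_per_generation)
            for s, d in zip(ss, dd):
                newborn.append(add(int(s), int(d), g))
        else:  # hierarchical: few sires, blocks of dams, full-sib litters
            n_sires = max(1, len(males) // 4)
            sires = rng.choice(males, size=n_sires, replace=False)
            k = 0
            while len(newborn) < spec.n_per_generation:
                s = int(sires[k % n_sires])
                d = int(females[rng.integers(len(females))])
                for _ in range(spec.offspring_per_mating):
                    if len(newborn) >= spec.n_per_generation:
                        break
                    newborn.append(add(s, d, g))
                k += 1
        prev = newborn

    return pd.DataFrame(
        {"animal": animal, "sire": sire, "dam": dam, "sex": sex, "generation": gen}
    )
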