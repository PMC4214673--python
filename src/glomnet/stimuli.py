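"""Synthetic odor stimuli: combinatorial panels, concentration series, morphs.

An odorant is represented by its pattern of receptor affinities across
glomeruli (the combinatorial code): a row of the sensitivity matrix S with
i.i.d. uniform entries on [0, 40] pA. The receptor response to odor i at
dimensionless concentration c is R = S_i * c, saturated by a hard
componentwise ceiling at 40 pA. The standard panel is 6 odors (labelled
A-F) x 16 glomeruli; the concentration series is {0.4, 0.6, 0.8, 1.0,
1.2, 1.4}; the morphing series is the 21-step convex interpolation between
odors C and E at concentration 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLIP_PA",
    "CONCENTRATIONS",
    "OdorPanel",
    "Stimulus",
    "StimulusSet",
    "generate_odor_panel",
    "stimulus_from_odor",
    "build_experiment1",
    "build_morph_series",
]

CLIP_PA = 40.0
CONCENTRATIONS = (0.4, 0.6, 0.8, 1.0, 1.2, 1.4)
_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class OdorPanel:
    """Sensitivity matrix S (odors x glomeruli, pA per unit concentration)."""

    S: np.ndarray
    labels: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2:
            raise ValueError("S must be 2-D (odors x glomeruli)")
        if (self.S < 0).any() or (self.S > CLIP_PA).any():
            raise ValueError(f"sensitivities must lie in [0, {CLIP_PA}] pA")
        if len(self.labels) != self.S.shape[0]:
            raise ValueError("one label per odor required")

    @property
    def n_odors(self) -> int:
        return self.S.shape[0]

    @property
    def n_glomeruli(self) -> int:
        return self.S.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.S[self.labels.index(label)]

    def to_text(self, path) -> None:
        header = (f"seed={self.seed} units=pA clip={CLIP_PA} "
                  f"labels={','.join(self.labels)}")
        np.savetxt(path, self.S, delimiter="\t", header=header)

    @classmethod
    def from_text(cls, path) -> "OdorPanel":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        S = np.loadtxt(path, delimiter="\t", ndmin=2)
        seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
        return cls(S=S, labels=meta["labels"].split(","), seed=seed)


@dataclass(frozen=True)
class Stimulus:
    """One exposure: odor label, concentration factor, current vector (pA)."""

    odor: str
    concentration: float
    R: np.ndarray


@dataclass
class StimulusSet:
    """An ordered collection of stimuli sharing one glomerular dimension."""

    stimuli: list[Stimulus]

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def __getitem__(self, i) -> Stimulus:
        return self.stimuli[i]

    @property
    def R(self) -> np.ndarray:
        """Stacked current vectors, shape (n_stimuli, n_glomeruli)."""
        return np.stack([s.R for s in self.stimuli])

    @property
    def odors(self) -> np.ndarray:
        return np.array([s.odor for s in self.stimuli])

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s.concentration for s in self.stimuli])

    def to_text(self, path) -> None:
        G = self.stimuli[0].R.size
        with open(path, "w") as fh:
            fh.write(f"# units=pA clip={CLIP_PA}\n")
            fh.write("odor\tconcentration\t"
                     + "\t".join(f"R{g}" for g in range(G)) + "\n")
            for s in self.stimuli:
                fh.write(f"{s.odor}\t{s.concentration:g}\t"
                         + "\t".join(f"{x:.6f}" for x in s.R) + "\n")

    @classmethod
    def from_text(cls, path) -> "StimulusSet":
        stimuli = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("odor\t"):
                    continue
                parts = line.rstrip("\n").split("\t")
                stimuli.append(Stimulus(parts[0], float(parts[1]),
                                        np.array([float(x) for x in parts[2:]])))
        return cls(stimuli)


def generate_odor_panel(n_odors: int = 6, n_glomeruli: int = 16,
                        seed: int | None = 0) -> OdorPanel:
    """Draw an i.i.d. uniform(0, 40 pA) sensitivity panel, reproducibly."""
    if n_odors < 1 or n_glomeruli < 1:
        raise ValueError("n_odors and n_glomeruli must be at least 1")
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.0, CLIP_PA, size=(n_odors, n_glomeruli))
    labels = [_LABELS[i % 26] + (str(i // 26) if i >= 26 else "")
              for i in range(n_odors)]
    return OdorPanel(S=S, labels=labels, seed=seed)


def stimulus_from_odor(S_row: np.ndarray, concentration: float) -> np.ndarray:
    """Receptor current for one odor at one concentration: min(S*c, 40) pA."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return np.minimum(np.asarray(S_row, dtype=float) * concentration, CLIP_PA)


def build_experiment1(panel: OdorPanel,
                      concentrations=CONCENTRATIONS) -> StimulusSet:
    """The odors x concentrations panel: odor-major, ascending concentration.

    With the default 6-odor panel and 6 concentrations this yields the
    36-stimulus set of the identity/concentration experiment.
    """
    stimuli = [Stimulus(lab, float(c), stimulus_from_odor(panel.S[i], c))
               for i, lab in enumerate(panel.labels)
               for c in concentrations]
    return StimulusSet(stimuli)


def build_morph_series(panel: OdorPanel, odor_from: str = "C",
                       odor_to: str = "E", n_steps: int = 21) -> StimulusSet:
    """Binary-mixture morphing series between two pure odors.

    Step j mixes the two endpoint responses (both at concentration factor 1)
    as (1 - alpha_j) * R_from + alpha_j * R_to with alpha on a uniform grid
    from 0 to 1, so the series runs from the pure first odor to the pure
    second odor; saturation is applied after mixing. Mixtures are labelled
    ``mix``; their ``concentration`` field stores alpha.
    """
    R_from = stimulus_from_odor(panel.row(odor_from), 1.0)
    R_to = stimulus_from_odor(panel.row(odor_to), 1.0)
    alphas = np.linspace(0.0, 1.0, n_steps)
    stimuli = [Stimulus("mix", float(a),
                        np.minimum((1.0 - a) * R_from + a * R_to, CLIP_PA))
               for a in alphas]
    return StimulusSet(stimuli)
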