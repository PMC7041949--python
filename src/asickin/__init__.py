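"""asickin: kinetics, fluctuation analysis and structural metrics for
acid-sensing ion channel desensitization studies.

Submodules
----------
sweeps
    Sweep/SweepBlock data model, TSV and HDF5 formats, epoch segmentation.
gating
    Deterministic Markov kinetic-scheme engine and protocol simulations.
synth
    Synthetic patch-clamp data generators (stochastic ensembles, noise,
    rundown, solution exchange, closed-form recovery/decay generators).
recovery
    Paired-pulse recovery-from-desensitization measurement and fitting.
nsfa
    Non-stationary fluctuation analysis pipeline.
kinetics
    Desensitization decay, rise time, sustained current, pH dose-response.
randomization
    Randomization tests and mean/SEM summaries.
structure
    Kabsch/RMSD/RMSF/dihedral/distance trajectory metrics.
"""

from . import gating, kinetics, nsfa, randomization, recovery, structure, sweeps, synth

__all__ = [
    "sweeps",
    "gating",
    "synth",
    "recovery",
    "nsfa",
    "kinetics",
    "randomization",
    "structure",
]

__version__ = "0.1.0"


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-operation seed: hash of (master seed, stable label).

    Adding pipeline stages never perturbs existing random streams because
    each stage draws from its own labelled stream.
    """
    import hashlib

    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
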