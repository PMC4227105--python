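import numpy as np
import pandas as pd
import pytest

from gliomethyl.model import BetaMatrix, ProbeManifest, SampleSheet, SignalSet


def make_manifest(rows):
    """Build a ProbeManifest from compact tuples:
    (probe_id, chrom, pos, design, channel, genes, feature, island, snp)."""
    df = pd.DataFrame(
        rows,
        columns=["probe_id", "chromosome", "position", "design_type", "channel",
                 "genes", "gene_feature", "island_relation", "snp_flag"],
    ).set_index("probe_id")
    df["genes"] = [tuple(sorted(set(g))) for g in df["genes"]]
    return ProbeManifest(df)


def make_beta(values, probes=None, samples=None, detection_p=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:04d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    beta = pd.DataFrame(values, index=probes, columns=samples)
    detp = None
    if detection_p is not None:
        detp = pd.DataFrame(np.asarray(detection_p, dtype=float),
                            index=probes, columns=samples)
    return BetaMatrix(beta=beta, detection_p=detp)


def make_sheet(pairs, normals=("N1", "N2", "N3", "N4")):
    """pairs: list of (pair_id, grade_early, grade_late[, idh1])."""
    rows = []
    for entry in pairs:
        pid, ge, gl = entry[:3]
        idh1 = entry[3] if len(entry) > 3 else "wt"
        rows.append([f"{pid}E", pid, "Early", ge, idh1, "wt", "sGBM"])
        rows.append([f"{pid}L", pid, "Late", gl, idh1, "wt", "sGBM"])
    for n in normals:
        rows.append([n, None, "Normal", "NA", "wt", "wt", "normal"])
    df = pd.DataFrame(
        rows, columns=["sample_id", "pair_id", "role", "who_grade",
                       "idh1_status", "idh2_status", "cohort"]
    ).set_index("sample_id")
    return SampleSheet(df)


@pytest.fixture
def tiny_manifest():
    return make_manifest([
        ("cg0001", "7", 25000, "II", "Both", ("GNMT",), "TSS200", "Island", False),
        ("cg0002", "7", 26000, "I", "Grn", ("GNMT",), "Body", "N_Shore", False),
        ("cg0003", "X", 5000, "I", "Red", ("ALS2CL",), "TSS1500", "OpenSea", True),
        ("cg0004", "22", 100, "II", "Both", (), "Intergenic", "S_Shelf", False),
        ("cg0005", "1", 900, "I", "Red", ("WNK2", "GNMT"), "UTR5", "Island", False),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort shared across tests (seed 11)."""
    from gliomethyl.simulate import SimulationConfig, generate_cohort, generate_manifest

    cfg = SimulationConfig(seed=11)
    manifest = generate_manifest(cfg)
    beta, sheet, truth = generate_cohort(cfg, manifest)
    return cfg, manifest, beta, sheet, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down cohort (4k probes) for fast structural tests."""
    from gliomethyl.simulate import SimulationConfig, generate_cohort, generate_manifest

    cfg = SimulationConfig(seed=7, n_probes=4000, n_genes=400,
                           n_grade_genes=20, n_conserved_genes=10)
    manifest = generate_manifest(cfg)
    beta, sheet, truth = generate_cohort(cfg, manifest)
    return cfg, manifest, beta, sheet, truth
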