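"""Shared fixtures: the documented synthetic panel, generated once per session."""

import numpy as np
import pytest

from domestiscan import simdata
from domestiscan.scan import run_scan
from domestiscan.variantio import GenotypeMatrix, filter_sites, INBRED, WILD


@pytest.fixture(scope="session")
def sim_config():
    return simdata.SimConfig()


@pytest.fixture(scope="session")
def bundle(sim_config):
    return simdata.generate_bundle(sim_config)


@pytest.fixture(scope="session")
def filtered_panel(bundle):
    gm, sites = filter_sites(bundle["gm"], bundle["sites"])
    return gm, sites


@pytest.fixture(scope="session")
def scan_results(bundle, filtered_panel, sim_config):
    gm, sites = filtered_panel
    return run_scan(gm, sites, bundle["genes"], sim_config.chrom_lengths())


def toy_matrix(gt_rows, groups=None):
    """Build a small GenotypeMatrix from a list of per-sample genotype lists.

    ``gt_rows[i][j]`` is an (a, b) allele-index pair or None for missing.
    """
    n_samples = len(gt_rows)
    n_sites = len(gt_rows[0])
    gt = np.zeros((n_samples, n_sites, 2), dtype=np.int16)
    for i, row in enumerate(gt_rows):
        for j, pair in enumerate(row):
            gt[i, j] = (-1, -1) if pair is None else pair
    samples = [f"s{i}" for i in range(n_samples)]
    if groups is None:
        groups = {s: WILD for s in samples}
    else:
        groups = {s: g for s, g in zip(samples, groups)}
    return GenotypeMatrix(samples, groups, gt)
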