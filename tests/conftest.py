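"""Shared fixtures: a wired biobank on a temp lake, cohorts, toy apps."""

from __future__ import annotations

import pytest

from biobank import Biobank
from biobank.fixtures import (
    CohortSpec,
    install_toy_apps,
    make_cohort,
    make_raw_files,
)


@pytest.fixture()
def bank(tmp_path):
    bank = Biobank(lake_root=tmp_path / "lake")
    yield bank
    bank.close()


@pytest.fixture()
def project(bank):
    return bank.get_or_create_project("P1")


@pytest.fixture()
def toy_apps(bank):
    return install_toy_apps(bank.apps)


@pytest.fixture()
def cohort(bank, project):
    return make_cohort(bank.store, CohortSpec(n_individuals=3, paired=True,
                                              seed=1), project)


def import_cohort(bank, cohort, tmp_path, reads_per_file=20, seed=1):
    """Deposit synthetic FASTQ for a cohort and import it; returns assets."""
    deposit = make_raw_files(cohort.experiments, tmp_path / "deposit",
                             reads_per_file=reads_per_file, seed=seed)
    scan = bank.lake.scan_and_match(deposit, cohort.experiments)
    return bank.lake.import_data(scan, actor="admin")


@pytest.fixture()
def imported_cohort(bank, project, cohort, tmp_path):
    import_cohort(bank, cohort, tmp_path)
    return cohort


def make_user(bank, username, roles=(), is_admin=False):
    return bank.store.create_record("user", {
        "username": username, "roles": list(roles), "is_admin": is_admin,
    }, actor="admin")
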