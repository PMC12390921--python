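import pytest

from saltcost import build_ethiopia_fixture, compute_report


@pytest.fixture(scope="session")
def fixture_books():
    books, _manifest = build_ethiopia_fixture()
    return books


@pytest.fixture(scope="session")
def fixture_manifest():
    _books, manifest = build_ethiopia_fixture()
    return manifest


@pytest.fixture(scope="session")
def fixture_reports(fixture_books):
    """Cost reports for all 8 books, expansions incremental to iodized."""
    reports = {}
    for scenario in ("s1", "s2"):
        base = compute_report(fixture_books[(scenario, "iodized")])
        reports[(scenario, "iodized")] = base
        for program in ("dual", "triple", "quad"):
            reports[(scenario, program)] = compute_report(
                fixture_books[(scenario, program)], baseline=base
            )
    return reports
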