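import numpy as np
import pytest

from mmisurv.life_tables import (
    LifeTableCoverageError,
    LifeTableStructureError,
    cumulative_expected_hazard,
    expected_hazard,
    expected_survival,
    read_life_table,
    write_life_table,
)

from conftest import flat_table

TOY = """age,year,sex,stratum,rate
70,2010,male,all,0.01
70,2011,male,all,0.012
71,2010,male,all,0.013
71,2011,male,all,0.014
"""


def _write(tmp_path, text, name="lt.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_toy_file_reports_ranges(tmp_path):
    table = read_life_table(_write(tmp_path, TOY))
    assert table.age_range == (70, 71)
    assert table.year_range == (2010, 2011)
    assert table.rates.size == 4
    assert float(table.rate_at(70, 2011, "male", "all")[0]) == 0.012


def test_missing_cell_is_structural_error(tmp_path):
    broken = "\n".join(TOY.strip().splitlines()[:-1]) + "\n"
    with pytest.raises(LifeTableStructureError, match=r"age=71.*year=2011"):
        read_life_table(_write(tmp_path, broken))


def test_negative_rate_rejected(tmp_path):
    bad = TOY.replace("0.012", "-0.01")
    with pytest.raises(LifeTableStructureError, match="negative rate"):
        read_life_table(_write(tmp_path, bad))


def test_column_map_and_tab_delimited(tmp_path):
    text = TOY.replace(",", "\t").replace("stratum", "quintile")
    table = read_life_table(_write(tmp_path, text), column_map={"quintile": "stratum"})
    assert table.age_range == (70, 71)


def test_qx_conversion(tmp_path):
    table_h = read_life_table(_write(tmp_path, TOY, "a.csv"))
    table_q = read_life_table(_write(tmp_path, TOY, "b.csv"), rate_type="qx")
    q = 0.01
    assert table_q.rate_at(70, 2010, "male", "all")[0] == pytest.approx(-np.log(1 - q))
    assert table_h.rate_at(70, 2010, "male", "all")[0] == pytest.approx(q)


def test_round_trip(tmp_path, life_table):
    p = tmp_path / "out.csv"
    write_life_table(life_table, p)
    back = read_life_table(p)
    assert back.age_range == life_table.age_range
    np.testing.assert_allclose(back.rates, life_table.rates)


def test_expected_hazard_attained_age_lookup(tmp_path):
    table = read_life_table(_write(tmp_path, TOY))
    # a=68, y=2008, t=2 -> cell (70, 2010)
    assert expected_hazard(table, 68, 2008, "male", "all", 2.0)[0] == pytest.approx(0.01)


def test_expected_hazard_clamps_age_not_year(tmp_path):
    table = read_life_table(_write(tmp_path, TOY))
    # attained age 102 clamps to the max age row
    assert expected_hazard(table, 99, 2008, "male", "all", 3.0)[0] == pytest.approx(0.014)
    with pytest.raises(LifeTableCoverageError, match="2020"):
        expected_hazard(table, 60, 2008, "male", "all", 12.0)


def test_expected_hazard_constant_within_cell(tmp_path):
    table = read_life_table(_write(tmp_path, TOY))
    vals = [expected_hazard(table, 70, 2010, "male", "all", t)[0] for t in (0.0, 0.3, 0.99)]
    assert len(set(np.round(vals, 15))) == 1


def test_expected_survival_closed_forms():
    table = flat_table(0.01)
    assert expected_survival(table, 70, 2005, "male", "3", 5.0) == pytest.approx(
        np.exp(-0.05), rel=1e-12
    )
    assert expected_survival(table, 70, 2005, "male", "3", 0.0) == 1.0


def test_expected_survival_two_cells():
    # rates 0.01 at age 70, 0.02 at age 71+, one year in each
    table = flat_table(0.01)
    rates = table.rates.copy()
    rates[:, :, 71 - table.ages[0] :, :] = 0.02
    from mmisurv.life_tables import LifeTable

    table2 = LifeTable(table.ages, table.years, table.sexes, table.strata, rates)
    s = expected_survival(table2, 70, 2005, "male", "3", 2.0)
    assert s == pytest.approx(np.exp(-0.03), rel=1e-12)


def test_cumulative_hazard_matches_riemann_oracle(life_table):
    # independent fine-grid Riemann sum over the piecewise-constant cells
    age, year, t = 67.4, 2006.3, 5.7
    exact = cumulative_expected_hazard(life_table, age, year, "male", "4", t)
    m = 400_000
    u = (np.arange(m) + 0.5) * t / m
    riemann = life_table.rate_at(age + u, year + u, "male", "4").mean() * t
    assert exact == pytest.approx(riemann, rel=5e-5)
    # non-increasing survival on a grid
    grid = np.linspace(0.0, 8.0, 50)
    s = np.exp(-np.asarray(cumulative_expected_hazard(life_table, age, year, "male", "4", grid)))
    assert np.all(np.diff(s) <= 1e-15)


def test_cumulative_hazard_exact_cell_products(life_table):
    """Exactness: integral equals the sum of rate x duration over cells."""
    age, year, t = 67.4, 2006.3, 4.2
    got = cumulative_expected_hazard(life_table, age, year, "male", "2", t)
    # independent cell walk
    bounds = sorted(
        {0.0, t}
        | {b for k in range(8) for b in (np.ceil(age) - age + k, np.ceil(year) - year + k)}
    )
    bounds = [b for b in bounds if 0.0 <= b <= t]
    total = 0.0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        total += life_table.rate_at(age + lo, year + lo, "male", "2")[0] * (hi - lo)
    assert got == pytest.approx(total, rel=1e-10)
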