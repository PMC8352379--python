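"""GNR-vs-saline statistical comparison at each wavelength.

Two-tailed pooled-variance Student t-tests on the per-animal maximum
temperature and fitted time constant, per wavelength, at alpha = 0.05.
"""

from pathlib import Path

from pttherm.io import read_results, write_results
from pttherm.pipeline import group_tests

OUT = Path("results")


def main() -> None:
    fits = read_results(OUT / "fits.csv")
    tests = group_tests(fits[fits["converged"]], alpha=0.05)
    write_results(tests, OUT / "t_tests.csv")
    print(tests.round(5).to_string(index=False))
    sig = tests[tests.significant]
    print(f"\n{len(sig)}/{len(tests)} comparisons significant at alpha=0.05")


if __name__ == "__main__":
    main()
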