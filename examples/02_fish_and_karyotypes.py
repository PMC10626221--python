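"""FISH tallies, cutoffs, and ISCN karyotype parsing on the worked-example case.

Recomputes marrow FISH percentages from raw positive/scored cell counts,
flags them against the probe-specific cutoff table, and parses the serial
diagnostic karyotype strings (including idem/sl stemline references and the
doubled sl x 2 clone).
"""

from hemaseq.cytogenetics import (apply_cutoff, format_ratio, load_default_cutoffs,
                                  parse_iscn, ratio_nonpc_pc, tally_fish)
from hemaseq.datasets import KARYOTYPES, case_fish_tallies

cutoffs = load_default_cutoffs()

print("specimen 1, polysomy 19 probe (TCF3 3 copies):")
pct_tnc = tally_fish(44, 200)
flag = apply_cutoff(pct_tnc, "TCF3 3 copies", 200, cutoffs)
print(f"  % in TNCs = {pct_tnc} (44/200), {flag}")
print(f"  % in PCs  = {tally_fish(19, 20)} (19/20)")
print(f"  non-PC:PC = {format_ratio(ratio_nonpc_pc(21, 23))} (21:23)")

print("\nspecimen 3, CDKN2A tetrasomy: "
      f"{tally_fish(2, 300)}% -> {apply_cutoff(tally_fish(2, 300), 'CDKN2A tetrasomy', 300, cutoffs)}")

print("\nkaryotypes:")
for spec, text in KARYOTYPES.items():
    kt = parse_iscn(text)
    print(f"  {spec}: {len(kt.clones)} clones")
    for i, clone in enumerate(kt.clones):
        abs_ = [a.render() for a in kt.resolved_aberrations(i)]
        print(f"    modal {clone.modal_count} [{clone.cell_count} cells] "
              f"{'(composite) ' if clone.composite else ''}{abs_ or 'normal'}")

n_cells = sum(c.tally.scored for probes in case_fish_tallies().values()
              for cells in probes.values() for k, c in cells.items() if k == "TNC")
print(f"\ntotal TNC cells scored across specimens/probes: {n_cells}")
# Percentages are rounded half-up to one decimal as in clinical reports; a
# "below_cutoff" flag means the signal is within the probe's background range.
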