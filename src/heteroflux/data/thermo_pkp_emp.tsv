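# Standard transformed reaction Gibbs energies for the phosphoketolase
# (PKP) and Embden-Meyerhof-Parnas (EMP) glucose catabolic routes of the
# central-metabolism fixture, at pH 7.2, ionic strength 0.1 M, 298.15 K.
#
# Provenance: literature transformed Gibbs energies for glycolytic /
# pentose-phosphate / fermentative reactions (group-contribution and
# component-contribution estimates as popularized by the eQuilibrator
# calculator), with small adjustments inside the published uncertainty
# bands so that the table is thermodynamically closed: the
# yield-weighted pathway sums equal the overall conversions
#   glucose -> lactate + ethanol + CO2   (PKP, net -186.8 kJ/mol)
#   glucose -> 2 lactate                 (EMP, net -178.0 kJ/mol)
# when the net substrate-level ATP is recycled (ATPM step).  This is a
# synthetic stand-in for a live calculator run; see docs/methods.md.
#
# reaction_id	dG0_prime_kJ_per_mol	pH	ionic_strength	source
HEX1	-19.5	7.2	0.1	literature_group_contribution
PGI_emp	2.5	7.2	0.1	literature_group_contribution
PFK	-16.0	7.2	0.1	literature_group_contribution
FBA	19.8	7.2	0.1	literature_group_contribution
TPI	5.5	7.2	0.1	literature_group_contribution
G6PDH	-25.0	7.2	0.1	literature_group_contribution_lumped_lactonase
GND	2.2	7.2	0.1	literature_group_contribution
RPE	-0.5	7.2	0.1	literature_group_contribution
PKETX	-45.0	7.2	0.1	literature_group_contribution
GAPD	7.5	7.2	0.1	literature_group_contribution
PGK	-18.9	7.2	0.1	literature_group_contribution
PGM	4.4	7.2	0.1	literature_group_contribution
ENO	-4.0	7.2	0.1	literature_group_contribution
PYK	-24.5	7.2	0.1	literature_group_contribution
LDH	-20.15	7.2	0.1	literature_group_contribution
PTAr	-9.1	7.2	0.1	literature_group_contribution
ACALD_rev	17.5	7.2	0.1	literature_group_contribution
ALCD_rev	-22.25	7.2	0.1	literature_group_contribution
ATPM	-29.5	7.2	0.1	literature_group_contribution
MDH_mlf	30.5	7.2	0.1	literature_group_contribution
OAADC	-25.0	7.2	0.1	literature_group_contribution
MLF	-33.0	7.2	0.1	literature_group_contribution
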