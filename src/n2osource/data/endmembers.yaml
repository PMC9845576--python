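# Literature endmember signatures of freshly produced N2O and the net
# isotope effects of N2O -> N2 reduction, for the dual-isotope
# (d15N-SP vs d18O) mapping approach.
#
# Values are means +/- SD in permil compiled from pure-culture and
# controlled-incubation studies of the four microbial processes:
#   bD  heterotrophic bacterial denitrification
#   fD  fungal denitrification
#   nD  nitrifier denitrification
#   Ni  nitrification (NH2OH oxidation route)
# d18O values of bD, fD and nD are expressed for production from water
# at 0 permil VSMOW and must be shifted by the measured d18O of the
# site water (adjust_for_water) before mapping; Ni derives its oxygen
# from atmospheric O2 and is never adjusted.
#
# This table is deliberately an editable configuration: revise it when
# the compilation literature is updated, and cite your revision.  Every
# mapping result records a hash of the table actually used.
version: 1
endmembers:
  bD: {sp: -1.6, sp_sd: 3.5, d18o: 17.5, d18o_sd: 4.6}
  fD: {sp: 35.1, sp_sd: 3.1, d18o: 39.8, d18o_sd: 4.0}
  nD: {sp: -3.1, sp_sd: 5.0, d18o: 21.8, d18o_sd: 4.1}
  Ni: {sp: 31.4, sp_sd: 4.2, d18o: 35.6, d18o_sd: 5.0}
reduction:
  # Net (apparent) isotope effects of N2O reduction on the residual
  # N2O, permil; both negative (the residual gets enriched), their
  # ratio is the slope of the reduction line in the map.
  eps_sp: -5.9
  eps_sp_sd: 1.5
  eps_o: -15.4
  eps_o_sd: 3.5
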