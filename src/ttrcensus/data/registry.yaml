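# Domain registry for the TTR census.
#
# This list is an editable stand-in seeded with common helix-turn-helix-family
# DNA-binding models and widespread signal-transduction domain models; edit it
# to match the annotation vocabulary of your own domain calls.
dna_binding:
  - HTH_1
  - HTH_8
  - HTH_AraC
  - HTH_Crp_2
  - GerE
  - Trans_reg_C
  - LytTR
  - MerR
  - PadR
  - Fe_dep_repress
  - Sigma70_r4
  - ROS_MUCR
# two-component core domains; a TTR carrying any of these is a hybrid TTR
tcs_core:
  - Response_reg
  - HATPase_c
  - HisKA
# models whose presence places a protein in the signal-transduction repertoire
st_membership:
  - Response_reg
  - HATPase_c
  - HisKA
  - MCPsignal
  - GGDEF
  - EAL
  - PAS
  - Cache_1
  - GAF
  - Y_Y_Y
  - CHASE
  - sCache_2
  - HD
  - SpoIIE
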