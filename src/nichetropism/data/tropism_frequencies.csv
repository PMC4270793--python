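line_id,host,strain,frequency_percent
D_ananassae_wAna,D_ananassae,wAna,95
D_melanogaster_wMel,D_melanogaster,wMel,71
D_mauritiana_wMau,D_mauritiana,wMau,71
D_yakuba_wYak,D_yakuba,wYak,30
D_tropicalis_wWil,D_tropicalis,wWil,40
D_simulans_wRi,D_simulans,wRi,17
D_sechellia_wSh,D_sechellia,wSh,0
D_simulans_wNo,D_simulans,wNo,0
D_teissieri_wTei,D_teissieri,wTei,2.3
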