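>tm_p18599 5-hydroxytryptamine receptor 2A (UniProtKB P18599), N-terminal 100-residue fragment
MEILCEDNTSLSSIPNSLMQVDGDSGLYRNDFNSRDANSSDASNWTIDGENRTNLSFEGY
LPPTCLSILHLQEKNWSALLTAVVIILTIAGNILVIMAVS
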