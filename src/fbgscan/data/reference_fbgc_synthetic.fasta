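>FBG-C-syn synthetic tenascin-C FBG domain scaffold (reconstruction from published anchors, not the UniProt P24821 subsequence)
MTVAYITFETNDYNYQQHLWNIFVSGVWAIWVSEFGNYLDFPDLIAELPFPGEIWVIYVN
VEMYQFWWFFHNYHFLEIGLWLDHSWEGFPEIEYGWHVQDLLEGFFGPSSTSSNNSNAQN
QQTKTRYKLKTTNTQNTQTGPSSTTSKAAASSGPNSDSSISNTRSATKSNGPSFELEFLA
NLSYGHPQGWSFLSGFGHDSYGIISNPEVLLSHNVLNFRNLEGRRKRA
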