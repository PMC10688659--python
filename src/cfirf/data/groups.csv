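group_id,label,size
purveyors,Model purveyors,5
intermediaries,Intermediaries,7
tfm,Their Futures Matter,6
dcj,Department of Communities and Justice,6
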